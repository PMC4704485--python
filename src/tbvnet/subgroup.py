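"""Small-brain / big-brain gene-relevance classification.

Within a diagnostic group, samples split at an age-adjusted trait residual
of 0 cc into "smaller" (< 0) and "bigger" (>= 0; ties broken upward) brain
subgroups.  For a designated gene list (typically PPI-mapped hub genes) the
full-group gene significance (GS-ALL) sets a threshold — the lowest |GS-ALL|
of the list — and each gene's subgroup GS (GS-SM / GS-BG) is classified as
*retained* when it still reaches that threshold and *lost* otherwise.
Candidate genes outside the list that newly exceed the threshold in a
subgroup are flagged *gained*.
"""

from __future__ import annotations

import pandas as pd

from .gene_metrics import gene_significance

__all__ = ["split_samples_by_residual", "classify_gene_relevance"]


def split_samples_by_residual(
    samples: pd.DataFrame, group: str = "all"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a group's samples by the sign of the trait residual.

    Residual < 0 -> "smaller"; residual >= 0 -> "bigger" (zeros upward).
    """
    sel = samples if group == "all" else samples[samples["group"] == group]
    resid = sel["tbv_residual_cc"].astype(float)
    if resid.isna().any():
        raise ValueError("trait residuals missing; run age_adjust_trait first")
    small = sel[resid < 0]
    big = sel[resid >= 0]
    if small.empty or big.empty:
        raise ValueError(
            f"degenerate residual split in group {group!r}: "
            f"{len(small)} smaller / {len(big)} bigger"
        )
    return small, big


def classify_gene_relevance(
    genes: list[str],
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    group: str = "all",
    candidates: list[str] | None = None,
) -> pd.DataFrame:
    """Classify genes as retaining/losing trait relevance in brain-size subgroups.

    ``genes`` is the designated hub list; the threshold is the minimum
    |GS-ALL| over that list.  ``candidates`` (default: none) are additional
    genes scanned for *gained* relevance — genes outside the hub list whose
    subgroup |GS| exceeds the threshold.

    Returns one row per gene with gs_all / gs_small / gs_big, the
    threshold, status_small / status_big in {retained, lost} (empty for
    pure candidates), and a ``gained`` flag.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to set a threshold")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"genes absent from expression: {missing[:10]}")
    candidates = [g for g in (candidates or []) if g not in set(genes)]

    small, big = split_samples_by_residual(samples, group)
    if len(small) < 4 or len(big) < 4:
        raise ValueError("both subgroups need >= 4 samples")

    all_genes = genes + [g for g in candidates if g in expr.index]
    sub = expr.loc[all_genes]
    gs_all = gene_significance(sub, samples if group == "all" else samples[samples["group"] == group], "all")["gs"]
    gs_small = gene_significance(sub, small, "all")["gs"]
    gs_big = gene_significance(sub, big, "all")["gs"]

    threshold = float(gs_all.loc[genes].abs().min())

    rows = []
    for g in all_genes:
        in_list = g in set(genes)
        st_small = st_big = ""
        gained = False
        if in_list:
            st_small = "retained" if abs(gs_small[g]) >= threshold else "lost"
            st_big = "retained" if abs(gs_big[g]) >= threshold else "lost"
        else:
            gained = bool(
                abs(gs_small[g]) >= threshold or abs(gs_big[g]) >= threshold
            )
        rows.append(
            {
                "gene": g,
                "in_hub_list": in_list,
                "gs_all": float(gs_all[g]),
                "gs_small": float(gs_small[g]),
                "gs_big": float(gs_big[g]),
                "threshold_all": threshold,
                "status_small": st_small,
                "status_big": st_big,
                "gained": gained,
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    out.attrs["n_small"] = len(small)
    out.attrs["n_big"] = len(big)
    return out
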