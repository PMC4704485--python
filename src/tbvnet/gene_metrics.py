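"""Gene-level network metrics and reorganization statistics.

Gene significance (GS): signed Pearson correlation of a gene's expression
with the age-adjusted trait, with Student asymptotic p-values.  Gene
connectivity (GC, kWithin): sum of a gene's adjacency weights to the other
genes of its module.  The GS-GC correlation difference between groups is
quantified with a population z statistic on Fisher-transformed
correlations (no p-value: every module gene is measured).  Hub/peripheral
contrasts use top-30 rankings and 2x2 odds ratios with Haldane-Anscombe
zero-cell correction and Woolf (log-scale) confidence intervals; the Fisher
exact p is always computed on the uncorrected table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import correlation_pvalue, permutation_pvalue, zdiff_population
from .coexpression import NON_MODULE_LABELS

__all__ = [
    "OddsRatioResult",
    "TopOverlap",
    "gene_significance",
    "intramodular_connectivity",
    "gs_gc_analysis",
    "rank_and_overlap",
    "contingency_odds_ratio",
    "map_hubs_to_ppi",
    "differential_expression",
]


def _group_trait(samples: pd.DataFrame, group: str) -> pd.Series:
    sel = samples if group == "all" else samples[samples["group"] == group]
    if len(sel) < 4:
        raise ValueError(f"need >= 4 samples in group {group!r}")
    trait = sel.set_index("sample_id")["tbv_residual_cc"].astype(float)
    if trait.isna().any():
        raise ValueError("trait residuals missing; run age_adjust_trait first")
    return trait


def gene_significance(
    expr: pd.DataFrame, samples: pd.DataFrame, group: str = "all"
) -> pd.DataFrame:
    """Per-gene signed correlation with the trait and its two-sided p-value.

    Constant genes yield missing GS with a warning.
    """
    trait = _group_trait(samples, group)
    x = expr[trait.index.tolist()].to_numpy(dtype=float)
    t = trait.to_numpy()
    n = len(t)
    xm = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)
    tz = (t - t.mean()) / t.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        gs = (xm @ tz) / n / sd
    n_const = int((sd == 0).sum())
    if n_const:
        warnings.warn(f"{n_const} constant gene(s): GS undefined", stacklevel=2)
    gs = np.where(sd == 0, np.nan, gs)
    p = np.array(
        [correlation_pvalue(r, n) if np.isfinite(r) else np.nan for r in gs]
    )
    return pd.DataFrame({"gene": expr.index, "gs": gs, "gs_p": p, "group": group, "n": n}).set_index("gene")


def intramodular_connectivity(
    adjacency: pd.DataFrame, partition: pd.Series
) -> pd.DataFrame:
    """kWithin: per-gene sum of adjacency to the other genes of its module.

    Unassigned genes get connectivity over the unassigned pool, flagged
    non-comparable.  Invariant to gene ordering.
    """
    partition = partition.reindex(adjacency.index)
    gc = pd.Series(0.0, index=adjacency.index, name="gc")
    for mod in partition.dropna().unique():
        genes = partition.index[partition == mod]
        sub = adjacency.loc[genes, genes].to_numpy(dtype=float)
        gc.loc[genes] = sub.sum(axis=1) - np.diag(sub)
    out = pd.DataFrame({"module": partition, "gc": gc})
    out["comparable"] = ~out["module"].isin(NON_MODULE_LABELS)
    return out


def gs_gc_analysis(
    gs_case: pd.Series,
    gs_control: pd.Series,
    gc: pd.Series,
    module_genes: list[str] | pd.Index,
) -> dict:
    """GS-GC correlation per group over a module's genes, and their z difference.

    Correlates |GS| with GC across the module genes in each group and
    returns (r_case, r_control, z_diff) with
    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), n = gene count.
    """
    genes = pd.Index(module_genes)
    if len(genes) < 4:
        raise ValueError("module must contain at least 4 genes")
    a = gs_case.loc[genes].abs().to_numpy(dtype=float)
    b = gs_control.loc[genes].abs().to_numpy(dtype=float)
    c = gc.loc[genes].to_numpy(dtype=float)
    r_case = float(np.corrcoef(a, c)[0, 1])
    r_control = float(np.corrcoef(b, c)[0, 1])
    z = zdiff_population(r_control, r_case, len(genes), len(genes))
    return {"r_case": r_case, "r_control": r_control, "z_diff": z, "n": len(genes)}


@dataclass
class TopOverlap:
    top_case: list[str]
    top_control: list[str]
    n_common: int
    n_different: int


def rank_and_overlap(
    metrics_case: pd.Series,
    metrics_control: pd.Series,
    k: int = 30,
    absolute: bool = True,
) -> TopOverlap:
    """Top-k genes per group by a metric, with overlap counts.

    Ranking is by |value| (or signed value with ``absolute=False``),
    descending; ties break lexicographically by gene identifier.
    """
    if len(metrics_case) < k or len(metrics_control) < k:
        raise ValueError(f"k={k} exceeds the number of ranked genes")

    def _top(s: pd.Series) -> list[str]:
        v = s.abs() if absolute else s
        order = sorted(v.index, key=lambda g: (-v[g], g))
        return list(order[:k])

    top_case = _top(metrics_case)
    top_control = _top(metrics_control)
    common = set(top_case) & set(top_control)
    return TopOverlap(top_case, top_control, len(common), k - len(common))


@dataclass
class OddsRatioResult:
    or_value: float
    ci_low: float
    ci_high: float
    fisher_p: float
    corrected: bool


def contingency_odds_ratio(
    table, zero_cell: str = "haldane", ci_level: float = 0.95
) -> OddsRatioResult:
    """Odds ratio of a 2x2 table with Woolf CI and Fisher exact p.

    With ``zero_cell="haldane"`` and any zero cell, 0.5 is added to all
    four cells before the OR and CI (the Fisher p always uses the
    uncorrected table).  CI: exp(ln OR +- z * sqrt(sum 1/cell)).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 array")
    if t.sum() == 0:
        raise ValueError("table is empty")
    a, b, c, d = t.ravel()
    if zero_cell not in ("haldane", "none"):
        raise ValueError(f"unknown zero_cell policy {zero_cell!r}")

    corrected = False
    w = t.copy()
    if (t == 0).any():
        if zero_cell == "haldane":
            w = t + 0.5
            corrected = True
        elif (a * d == 0) and (b * c == 0):
            raise ValueError("odds ratio undefined: zero cells in both diagonals")
    aw, bw, cw, dw = w.ravel()
    if bw * cw == 0:
        or_value = np.inf
        ci_low, ci_high = np.nan, np.inf
    else:
        or_value = (aw * dw) / (bw * cw)
        if (w == 0).any():
            ci_low, ci_high = 0.0, np.inf
        else:
            z = stats.norm.ppf(0.5 + ci_level / 2.0)
            se = np.sqrt((1.0 / w).sum())
            log_or = np.log(or_value)
            ci_low = float(np.exp(log_or - z * se))
            ci_high = float(np.exp(log_or + z * se))
    _, fisher_p = stats.fisher_exact(np.asarray(table, dtype=int), alternative="two-sided")
    return OddsRatioResult(
        or_value=float(or_value),
        ci_low=ci_low,
        ci_high=ci_high,
        fisher_p=float(fisher_p),
        corrected=corrected,
    )


def map_hubs_to_ppi(hub_genes: list[str], edges: pd.DataFrame) -> pd.DataFrame:
    """Map hub genes onto a protein-interaction edge list.

    Returns the hubs present in the network's node set with their degree
    (duplicate edges collapsed, self-loops ignored).  Empty intersection
    yields an empty frame with a warning.
    """
    import networkx as nx

    if len(edges) < 1:
        raise ValueError("edge list is empty")
    g = nx.Graph()
    for a_node, b_node in edges.iloc[:, :2].itertuples(index=False):
        if a_node != b_node:
            g.add_edge(str(a_node), str(b_node))
    mapped = [h for h in hub_genes if h in g]
    if not mapped:
        warnings.warn("no hub genes map into the PPI network", stacklevel=2)
    return pd.DataFrame(
        {"gene": mapped, "degree": [g.degree[h] for h in mapped]}
    ).set_index("gene")


def differential_expression(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene Welch two-sample t-test with a group-label permutation p.

    Returns (t, p, perm_p) per gene; perm_p = count / (n_perm + 1) where the
    count is of permuted |t| >= |t_obs|.
    """
    grp = samples.set_index("sample_id")["group"]
    case_ids = grp.index[grp == "case"].tolist()
    ctrl_ids = grp.index[grp == "control"].tolist()
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("both groups need >= 2 samples")
    x = expr[case_ids + ctrl_ids].to_numpy(dtype=float)
    n1, n2 = len(case_ids), len(ctrl_ids)

    def _welch(mat: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> np.ndarray:
        a, b = mat[:, idx1], mat[:, idx2]
        m1, m2 = a.mean(axis=1), b.mean(axis=1)
        v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        denom = np.sqrt(v1 / idx1.size + v2 / idx2.size)
        with np.errstate(invalid="ignore", divide="ignore"):
            return (m1 - m2) / denom

    idx1 = np.arange(n1)
    idx2 = np.arange(n1, n1 + n2)
    t_obs = _welch(x, idx1, idx2)
    v1 = x[:, idx1].var(axis=1, ddof=1) / n1
    v2 = x[:, idx2].var(axis=1, ddof=1) / n2
    with np.errstate(invalid="ignore", divide="ignore"):
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * stats.t.sf(np.abs(t_obs), df=df)

    rng = np.random.default_rng(seed)
    counts = np.zeros(x.shape[0], dtype=int)
    order = np.arange(n1 + n2)
    abs_obs = np.abs(t_obs)
    for _ in range(n_perm):
        rng.shuffle(order)
        t_perm = _welch(x, order[:n1], order[n1:])
        counts += np.abs(t_perm) >= abs_obs
    perm_p = np.array([permutation_pvalue(c, n_perm) for c in counts])
    return pd.DataFrame(
        {"t": t_obs, "p": p, "perm_p": perm_p}, index=expr.index
    )
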