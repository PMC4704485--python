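"""Module eigengene / gene-set association with the age-adjusted trait.

Pearson correlations with Student asymptotic p-values, Storey q-values
across modules, label-scrambling permutation nulls for each module's
association, group-label permutation tests for the difference in
correlation strength (Fisher zDiff), and percentile bootstrap confidence
intervals.  All permutation p-values follow count/(n_perm + 1); an exact 0
therefore means "< 1/(n_perm + 1)".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import corr_test, fisher_z, permutation_pvalue
from .coexpression import NON_MODULE_LABELS, EigengeneSet

__all__ = [
    "PermutationSpec",
    "module_trait_correlation",
    "storey_qvalues",
    "permutation_module_pvalue",
    "group_difference_permutation",
    "bootstrap_ci",
    "subnetwork_association",
]

TRAIT_COL = "tbv_residual_cc"


@dataclass
class PermutationSpec:
    """Permutation settings: iteration count, seed, statistic family."""

    n_perm: int = 10000
    seed: int = 0
    statistic: str = "abs_r"  # or "z_diff"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.statistic not in ("abs_r", "z_diff"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


def _group_samples(samples: pd.DataFrame, group: str) -> pd.DataFrame:
    if group == "all":
        sel = samples
    else:
        sel = samples[samples["group"] == group]
    if sel.empty:
        raise ValueError(f"no samples in group {group!r}")
    return sel


def _trait_vector(samples: pd.DataFrame, group: str) -> pd.Series:
    sel = _group_samples(samples, group)
    trait = sel.set_index("sample_id")[TRAIT_COL].astype(float)
    if trait.isna().any():
        raise ValueError("trait residuals missing; run age_adjust_trait first")
    return trait


def module_trait_correlation(
    me: EigengeneSet | pd.DataFrame,
    samples: pd.DataFrame,
    group: str = "all",
) -> pd.DataFrame:
    """Pearson r of each module eigengene with the age-adjusted trait.

    Returns a table (module, group, n, r, p); p from the Student asymptotic
    test with n - 2 degrees of freedom, two-sided.
    """
    me_df = me.me if isinstance(me, EigengeneSet) else me
    trait = _trait_vector(samples, group)
    if len(trait) < 4:
        raise ValueError(f"need >= 4 samples in group {group!r}, got {len(trait)}")
    rows = []
    for mod in me_df.index:
        v = me_df.loc[mod, trait.index].to_numpy(dtype=float)
        r, p = corr_test(v, trait.to_numpy())
        rows.append({"module": mod, "group": group, "n": len(trait), "r": r, "p": p})
    return pd.DataFrame(rows)


def storey_qvalues(
    pvals,
    lambdas: np.ndarray | None = None,
    method: str = "smoother",
) -> np.ndarray:
    """Storey q-values with pi0 estimated on a lambda grid.

    pi0(lambda) = mean(p > lambda) / (1 - lambda) on the grid
    {0, 0.05, ..., 0.90}; with ``method="smoother"`` a cubic smoothing
    spline of pi0(lambda) is evaluated at the largest lambda, clipped to
    (0, 1].  ``method="bh"`` forces pi0 = 1 (Benjamini-Hochberg fallback).
    q-values are monotone nondecreasing in the sorted p-values and <= 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.0, 0.9001, 0.05)
    if method == "bh":
        pi0 = 1.0
    else:
        pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
        if p.size < 20 or np.allclose(pi0_l, pi0_l[0]):
            pi0 = float(min(1.0, pi0_l[-1] if p.size >= 20 else 1.0))
        else:
            from scipy.interpolate import UnivariateSpline

            spl = UnivariateSpline(lambdas, pi0_l, k=3, s=len(lambdas) / 20.0)
            pi0 = float(spl(lambdas[-1]))
        pi0 = float(np.clip(pi0, 1.0 / p.size, 1.0)) if pi0 <= 0 else float(min(pi0, 1.0))
    order = np.argsort(p, kind="stable")
    n = p.size
    q_sorted = pi0 * n * p[order] / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _standardized(expr: pd.DataFrame, columns) -> np.ndarray:
    x = expr[list(columns)].to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = np.nan
    return (x - mu) / sd


def _first_pc(z: np.ndarray) -> np.ndarray:
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    if np.dot(me, z.mean(axis=0)) < 0:
        me = -me
    return me


def permutation_module_pvalue(
    expr: pd.DataFrame,
    partition: pd.Series,
    samples: pd.DataFrame,
    spec: PermutationSpec | None = None,
    group: str = "all",
) -> pd.DataFrame:
    """Label-scrambling permutation null for each module's trait association.

    Per iteration the gene -> module assignment is permuted (module sizes
    preserved), eigengenes are recomputed, and |r(ME, trait)| recorded; the
    p-value is #{|r_perm| >= |r_obs|} / (n_perm + 1).
    """
    spec = spec or PermutationSpec()
    partition = partition.reindex(expr.index)
    if partition.isna().any():
        raise ValueError("partition does not cover the expression matrix")
    trait = _trait_vector(samples, group)
    tz = trait.to_numpy()
    tz = (tz - tz.mean()) / tz.std()

    z = _standardized(expr, trait.index)
    z = np.nan_to_num(z)
    labels = partition.to_numpy()
    modules = [m for m in pd.unique(labels) if m not in NON_MODULE_LABELS]
    idx_of = {m: np.where(labels == m)[0] for m in modules}
    n = len(trait)

    # observed statistic uses the genuine module membership
    obs = {}
    for m in modules:
        me = _first_pc(z[idx_of[m]])
        mez = (me - me.mean()) / me.std()
        obs[m] = abs(float(mez @ tz) / n)

    rng = np.random.default_rng(spec.seed)
    counts = {m: 0 for m in modules}
    for _ in range(spec.n_perm):
        perm = rng.permutation(labels)
        for m in modules:
            rows = np.where(perm == m)[0]
            me = _first_pc(z[rows])
            sd = me.std()
            r = abs(float(((me - me.mean()) / (sd if sd > 0 else 1.0)) @ tz) / n)
            if r >= obs[m]:
                counts[m] += 1
    rows = [
        {
            "module": m,
            "group": group,
            "r_obs_abs": obs[m],
            "perm_p": permutation_pvalue(counts[m], spec.n_perm),
            "n_perm": spec.n_perm,
        }
        for m in modules
    ]
    return pd.DataFrame(rows)


def group_difference_permutation(
    values: pd.Series,
    samples: pd.DataFrame,
    spec: PermutationSpec | None = None,
) -> dict:
    """Fisher zDiff permutation test for a case/control correlation difference.

    ``values`` is a per-sample score (ME or subnetwork average) indexed by
    sample_id.  zDiff = atanh(r_case) - atanh(r_control); the null shuffles
    group labels; p = #{|zDiff_perm| >= |zDiff_obs|} / (n_perm + 1).
    """
    spec = spec or PermutationSpec()
    case = _trait_vector(samples, "case")
    control = _trait_vector(samples, "control")
    if len(case) < 4 or len(control) < 4:
        raise ValueError("both groups need >= 4 samples")

    v_case = values.loc[case.index].to_numpy(dtype=float)
    v_control = values.loc[control.index].to_numpy(dtype=float)

    def _zdiff(vc, tc, vk, tk) -> float:
        rc = np.corrcoef(vc, tc)[0, 1]
        rk = np.corrcoef(vk, tk)[0, 1]
        return float(fisher_z(rc) - fisher_z(rk))

    z_obs = _zdiff(v_case, case.to_numpy(), v_control, control.to_numpy())

    v_all = np.concatenate([v_case, v_control])
    t_all = np.concatenate([case.to_numpy(), control.to_numpy()])
    n_case = len(case)
    rng = np.random.default_rng(spec.seed)
    count = 0
    idx = np.arange(len(v_all))
    for _ in range(spec.n_perm):
        rng.shuffle(idx)
        ci, ki = idx[:n_case], idx[n_case:]
        z_perm = _zdiff(v_all[ci], t_all[ci], v_all[ki], t_all[ki])
        if abs(z_perm) >= abs(z_obs):
            count += 1
    return {
        "z_diff_obs": z_obs,
        "perm_p": permutation_pvalue(count, spec.n_perm),
        "n_case": n_case,
        "n_control": len(control),
        "n_perm": spec.n_perm,
    }


def bootstrap_ci(
    values: pd.Series,
    samples: pd.DataFrame,
    n_boot: int = 10000,
    seed: int = 0,
    group: str = "all",
    ci_level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the score-trait correlation in a group."""
    trait = _trait_vector(samples, group)
    if len(trait) < 8:
        raise ValueError(f"need >= 8 samples in group {group!r} for the bootstrap")
    v = values.loc[trait.index].to_numpy(dtype=float)
    t = trait.to_numpy()
    rng = np.random.default_rng(seed)
    n = len(t)
    rs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        vb, tb = v[idx], t[idx]
        if vb.std() == 0 or tb.std() == 0:
            rs[b] = np.nan
            continue
        rs[b] = np.corrcoef(vb, tb)[0, 1]
    lo, hi = np.nanpercentile(rs, [2.5, 97.5])
    return float(lo), float(hi)


def subnetwork_association(
    gene_set: list[str],
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    spec: PermutationSpec | None = None,
) -> dict:
    """Associate a gene set's average standardized expression with the trait.

    Returns per-group association records plus the case/control zDiff
    permutation result, all computed on the per-sample mean of the member
    genes' standardized expression.
    """
    present = [g for g in gene_set if g in expr.index]
    missing = [g for g in gene_set if g not in expr.index]
    if len(present) < 1:
        raise ValueError(f"no genes of the set found in expression: missing {missing[:10]}")
    if len(present) < 2 and len(gene_set) >= 2:
        raise ValueError(f"fewer than 2 genes mapped; missing {missing[:10]}")
    z = _standardized(expr.loc[present], expr.columns)
    avg = pd.Series(np.nanmean(z, axis=0), index=expr.columns, name="subnetwork_avg")

    records = {}
    for group in ("all", "case", "control"):
        trait = _trait_vector(samples, group)
        r, p = corr_test(avg.loc[trait.index].to_numpy(), trait.to_numpy())
        records[group] = {"n": len(trait), "r": r, "p": p}
    diff = group_difference_permutation(avg, samples, spec)
    return {
        "average": avg,
        "n_genes": len(present),
        "missing": missing,
        "association": records,
        "group_difference": diff,
    }
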