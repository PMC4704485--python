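"""Gene filtering, replicate handling, and age-adjustment of the trait.

The variance filter drops genes whose variance is significantly *below* the
median gene variance (one-sided chi-square test, lower tail), i.e. genes
carrying no usable intensity variation.  Genes missing in more than half of
the subjects are removed.  The trait (TBV, cc) is residualized on age with a
fixed-df cubic regression spline fit pooled across groups (a deterministic
stand-in for a generalized additive model with the same residualization
contract); residuals split at 0 into the "smaller"/"bigger" brain subgroups
used downstream.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["filter_genes", "collapse_replicates", "age_adjust_trait"]


def filter_genes(
    expr: pd.DataFrame,
    max_missing_frac: float = 0.5,
    variance_alpha: float = 0.05,
) -> pd.DataFrame:
    """Remove high-missingness and uninformative (low-variance) genes.

    A gene is removed when it is missing in more than ``max_missing_frac``
    of the samples, or when a one-sided chi-square test finds its variance
    significantly smaller than the median gene variance at level
    ``variance_alpha`` (lower-tail p < alpha => removed).  Order preserved.
    """
    if expr.empty:
        raise ValueError("empty expression matrix")
    vals = expr.to_numpy(dtype=float)
    n_samples = vals.shape[1]

    missing_frac = np.isnan(vals).sum(axis=1) / n_samples
    keep_missing = missing_frac <= max_missing_frac

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        variances = np.nanvar(vals, axis=1, ddof=1)
        n_obs = (~np.isnan(vals)).sum(axis=1)
    valid = keep_missing & (n_obs >= 2)
    if not valid.any():
        raise ValueError("empty after filtering: no gene passes the missingness rule")
    med = np.nanmedian(variances[valid])
    if med <= 0:
        keep_var = variances > 0
    else:
        dof = np.maximum(n_obs - 1, 1)
        stat = dof * variances / med
        p_lower = stats.chi2.cdf(stat, dof)
        keep_var = p_lower >= variance_alpha

    keep = valid & keep_var
    if not keep.any():
        raise ValueError("empty after filtering")
    return expr.loc[keep]


def _resolve_subject(sid: str, link: dict[str, str]) -> str:
    """Follow replicate_of links to the root subject; detect cycles."""
    seen = []
    cur = sid
    while cur in link:
        if cur in seen:
            raise ValueError(f"replicate cycle involving {cur!r}")
        seen.append(cur)
        cur = link[cur]
    return cur


def collapse_replicates(
    expr: pd.DataFrame, samples: pd.DataFrame, policy: str = "average"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse technical replicate arrays to one column per subject.

    ``policy="average"`` takes the per-gene mean across a subject's arrays;
    ``policy="pick_labeled"`` keeps the designated (root) array and drops
    the replicates.
    """
    if policy not in ("average", "pick_labeled"):
        raise ValueError(f"unknown replicate policy {policy!r}")
    link = {
        row.sample_id: row.replicate_of
        for row in samples.itertuples()
        if pd.notna(row.replicate_of)
    }
    unknown = set(link.values()) - set(samples["sample_id"])
    if unknown:
        raise ValueError(f"replicate_of points at unknown samples: {sorted(unknown)}")

    roots = {sid: _resolve_subject(sid, link) for sid in samples["sample_id"]}
    out_samples = samples[samples["sample_id"].map(lambda s: roots[s] == s)].copy()
    out_samples = out_samples.reset_index(drop=True)

    if policy == "pick_labeled":
        out_expr = expr[out_samples["sample_id"].tolist()]
    else:
        groups: dict[str, list[str]] = {}
        for sid, root in roots.items():
            groups.setdefault(root, []).append(sid)
        cols = {
            root: expr[members].mean(axis=1)
            for root, members in groups.items()
        }
        out_expr = pd.DataFrame(cols)[out_samples["sample_id"].tolist()]
        out_expr.index.name = expr.index.name
    return out_expr, out_samples


def _spline_basis(age: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic regression spline basis (patsy ``cr``) with df columns."""
    from patsy import dmatrix  # statsmodels dependency

    return np.asarray(
        dmatrix("cr(x, df=%d) - 1" % df, {"x": age}, return_type="matrix")
    )


def age_adjust_trait(
    samples: pd.DataFrame,
    method: str = "spline",
    df: int = 4,
    pooled: bool = True,
) -> pd.DataFrame:
    """Residualize the trait on age; store residuals in ``tbv_residual_cc``.

    Fits tbv ~ s(age) (cubic regression spline with ``df`` basis functions)
    or a straight line, pooled across groups by default, and stores mean-zero
    residuals.  The fitted trend's R^2 is recorded in ``attrs``.
    """
    if method not in ("spline", "linear"):
        raise ValueError(f"unknown method {method!r}")
    out = samples.copy()

    def _fit(rows: pd.Index) -> None:
        age = out.loc[rows, "age_years"].to_numpy(dtype=float)
        y = out.loc[rows, "tbv_cc"].to_numpy(dtype=float)
        n = len(age)
        if n < 8:
            raise ValueError(f"need >= 8 samples with age and trait, got {n}")
        if method == "linear":
            X = np.column_stack([np.ones(n), age])
        else:
            if df >= n:
                raise ValueError(f"spline df={df} must be < n={n}")
            X = np.column_stack([np.ones(n), _spline_basis(age, df)])
        if y.std() == 0:
            out.loc[rows, "tbv_residual_cc"] = 0.0
            return
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ beta
        resid = y - fitted
        out.loc[rows, "tbv_residual_cc"] = resid - resid.mean()
        tss = ((y - y.mean()) ** 2).sum()
        out.attrs.setdefault("age_adjustment", {})[
            "pooled" if pooled else str(out.loc[rows, "group"].iloc[0])
        ] = {
            "method": method,
            "df": df,
            "r2_trend": float(1.0 - (resid**2).sum() / tss) if tss > 0 else 0.0,
        }

    if pooled:
        _fit(out.index)
    else:
        for _, rows in out.groupby("group").groups.items():
            _fit(rows)
    return out
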