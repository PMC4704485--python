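"""Module preservation between a reference and a test expression dataset.

A reduced permutation-Z battery in the density/connectivity spirit of the
field's preservation statistics.  For every reference module (on the gene
intersection of the two datasets):

density (test-data) statistics
  * mean within-module adjacency,
  * proportion of expression variance explained by the test-data eigengene,
  * mean |kME| (gene-eigengene correlation);

connectivity statistics (reference side held fixed at the observed module)
  * correlation of (kWithin_ref, kWithin_test) over module genes,
  * correlation of the vectorized within-module correlation matrices.

Each statistic is standardized against random same-size gene samples drawn
from the test data: Z = (obs - mean_perm) / sd_perm.  Z_density and
Z_connectivity are medians of their statistic groups; Zsummary is their
mean.  medianRank is the median over statistics of the module's observed
rank (1 = most preserved).  Bands: Zsummary < 2 none, 2-10 moderate,
> 10 high.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .coexpression import NON_MODULE_LABELS

__all__ = ["module_preservation", "preservation_band"]

DENSITY_STATS = ("mean_adj", "prop_var_explained", "mean_abs_kme")
CONNECTIVITY_STATS = ("cor_kim", "cor_cor")


def preservation_band(zsummary: float) -> str:
    if zsummary > 10:
        return "high"
    if zsummary >= 2:
        return "moderate"
    return "none"


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def _module_stats(
    cor_test: np.ndarray,
    adj_test: np.ndarray,
    z_test: np.ndarray,
    cand: np.ndarray,
    ref_kim: np.ndarray,
    ref_corvec: np.ndarray,
) -> dict[str, float]:
    m = len(cand)
    sub_adj = adj_test[np.ix_(cand, cand)]
    mean_adj = (sub_adj.sum() - np.trace(sub_adj)) / (m * (m - 1))

    z = z_test[cand]
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    prop_var = float(s[0] ** 2 / (s**2).sum())
    me = vt[0]
    me = (me - me.mean()) / me.std()
    kme = (z @ me) / z.shape[1]
    mean_abs_kme = float(np.abs(kme).mean())

    kim_test = sub_adj.sum(axis=1) - np.diag(sub_adj)
    if np.std(kim_test) == 0 or np.std(ref_kim) == 0:
        cor_kim = 0.0
    else:
        cor_kim = float(np.corrcoef(ref_kim, kim_test)[0, 1])

    iu = np.triu_indices(m, k=1)
    test_corvec = cor_test[np.ix_(cand, cand)][iu]
    if np.std(test_corvec) == 0 or np.std(ref_corvec) == 0:
        cor_cor = 0.0
    else:
        cor_cor = float(np.corrcoef(ref_corvec, test_corvec)[0, 1])

    return {
        "mean_adj": float(mean_adj),
        "prop_var_explained": prop_var,
        "mean_abs_kme": mean_abs_kme,
        "cor_kim": cor_kim,
        "cor_cor": cor_cor,
    }


def module_preservation(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    partition_ref: pd.Series,
    power: int = 6,
    n_perm: int = 200,
    seed: int = 0,
    min_module_size: int = 10,
) -> pd.DataFrame:
    """Preservation record (Z_density, Z_connectivity, Zsummary, medianRank,
    band) per reference module evaluated in the test dataset.

    Modules retaining fewer than ``min_module_size`` genes on the gene
    intersection are skipped with a warning.  Deterministic under ``seed``.
    """
    common = ref_expr.index.intersection(test_expr.index)
    if len(common) < min_module_size:
        raise ValueError("too few shared genes between datasets")
    ref = ref_expr.loc[common]
    test = test_expr.loc[common]
    partition = partition_ref.reindex(common)

    cor_ref = np.corrcoef(_standardize_rows(ref.to_numpy(dtype=float)))
    cor_test = np.corrcoef(_standardize_rows(test.to_numpy(dtype=float)))
    adj_ref = np.abs(cor_ref) ** power
    adj_test = np.abs(cor_test) ** power
    z_test = _standardize_rows(test.to_numpy(dtype=float))

    modules = [
        m for m in pd.unique(partition.dropna()) if m not in NON_MODULE_LABELS
    ]
    pos = {g: i for i, g in enumerate(common)}
    rng = np.random.default_rng(seed)
    n_genes = len(common)

    obs_stats: dict[str, dict[str, float]] = {}
    z_stats: dict[str, dict[str, float]] = {}
    for mod in modules:
        genes = partition.index[partition == mod]
        if len(genes) < min_module_size:
            warnings.warn(
                f"module {mod!r} retains {len(genes)} genes (<{min_module_size}); skipped",
                stacklevel=2,
            )
            continue
        cand = np.array([pos[g] for g in genes])
        m = len(cand)
        sub_ref = adj_ref[np.ix_(cand, cand)]
        ref_kim = sub_ref.sum(axis=1) - np.diag(sub_ref)
        iu = np.triu_indices(m, k=1)
        ref_corvec = cor_ref[np.ix_(cand, cand)][iu]

        obs = _module_stats(cor_test, adj_test, z_test, cand, ref_kim, ref_corvec)
        null = {k: np.empty(n_perm) for k in obs}
        for b in range(n_perm):
            rnd = rng.choice(n_genes, size=m, replace=False)
            st = _module_stats(cor_test, adj_test, z_test, rnd, ref_kim, ref_corvec)
            for k, v in st.items():
                null[k][b] = v
        zs = {}
        for k in obs:
            mu = null[k].mean()
            sd = null[k].std(ddof=1)
            if sd < 1e-12:
                zs[k] = 0.0 if abs(obs[k] - mu) < 1e-12 else np.sign(obs[k] - mu) * 1e6
            else:
                zs[k] = (obs[k] - mu) / sd
        obs_stats[mod] = obs
        z_stats[mod] = zs

    if not obs_stats:
        raise ValueError("no module large enough for preservation analysis")

    all_stats = DENSITY_STATS + CONNECTIVITY_STATS
    kept = list(obs_stats)
    # observed-statistic ranks across modules (1 = most preserved)
    ranks = {}
    for stat in all_stats:
        vals = pd.Series({m: obs_stats[m][stat] for m in kept})
        ranks[stat] = vals.rank(ascending=False, method="min")

    rows = []
    for mod in kept:
        zd = float(np.median([z_stats[mod][s] for s in DENSITY_STATS]))
        zc = float(np.median([z_stats[mod][s] for s in CONNECTIVITY_STATS]))
        zsum = 0.5 * (zd + zc)
        med_rank = float(np.median([ranks[s][mod] for s in all_stats]))
        rows.append(
            {
                "module": mod,
                "n_genes": int((partition == mod).sum()),
                "Z_density": zd,
                "Z_connectivity": zc,
                "Zsummary": zsum,
                "medianRank": med_rank,
                "band": preservation_band(zsum),
            }
        )
    return pd.DataFrame(rows).set_index("module")
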