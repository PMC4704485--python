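"""Hypergeometric gene-set enrichment against a fixed background.

The background universe defaults to 21,405 genes.  For a query of size n
and a set of size K, the enrichment p is the upper-tail hypergeometric
probability P(X >= k) including the observed overlap k; q-values across
sets are Benjamini-Hochberg.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["hypergeometric_enrichment", "DEFAULT_BACKGROUND"]

DEFAULT_BACKGROUND = 21405


def hypergeometric_enrichment(
    query: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    background: int = DEFAULT_BACKGROUND,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query list in each gene set.

    Returns a table (set_name, k, K, n, N, p, q) sorted by p.  Raises when
    a set or the query exceeds the background universe.
    """
    query_set = set(query)
    n = len(query_set)
    if n > background:
        raise ValueError(f"query size {n} exceeds background {background}")
    rows = []
    for name, members in sets.items():
        members = set(members)
        K = len(members)
        if K > background:
            raise ValueError(f"set {name!r} size {K} exceeds background {background}")
        k = len(query_set & members)
        p = float(stats.hypergeom.sf(k - 1, background, K, n))
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": background, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
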