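"""Hypergeometric over-representation testing with BH correction.

A query list of n genes drawn from a universe of N genes is tested
against each gene set: with K set members in the universe and k of them
in the query, the p-value is the upper tail P(X >= k) for
X ~ Hypergeometric(N, K, n).  Only over-representation is tested.
P-values across sets are adjusted with the Benjamini-Hochberg step-up
procedure; the default significance cut-off is FDR 0.05.

The universe is the population the query was actually drawn from — in
this package, the genes surviving preprocessing — not the whole genome.
Set members absent from the universe are dropped before computing K.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataError
from .io import GeneSetCollection


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    ``N`` universe size, ``K`` set size in the universe, ``n`` query
    size, ``k`` overlap.  The survival function is evaluated in log-space
    internally by scipy, so tiny tails are representable.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise DataError(
            f"inconsistent counts for hypergeometric test: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving.

    q_i = min over j with p_(j) >= p_(i) of min(1, p_(j) * m / rank_j).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query,
    sets: GeneSetCollection,
    universe,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Test every set in a collection for over-representation in ``query``.

    ``query`` must be a subset of ``universe``; each set is intersected
    with the universe before testing.  Returns one row per set, sorted by
    p ascending (set name breaks ties), with columns ``set``, ``k``,
    ``K``, ``n``, ``N``, ``p``, ``q``, ``significant``.
    """
    universe = list(dict.fromkeys(universe))
    uni = set(universe)
    query = list(dict.fromkeys(query))
    outside = [g for g in query if g not in uni]
    if outside:
        raise DataError(f"query gene(s) outside the universe: {outside[:10]}")
    qset = set(query)
    N, n = len(uni), len(qset)
    rows = []
    for set_name, members in sets.items():
        members_u = members & uni
        K = len(members_u)
        k = len(members_u & qset)
        p = hypergeom_upper(k, K, n, N) if K else 1.0
        rows.append({"set": set_name, "k": k, "K": K, "n": n, "N": N, "p": p})
    table = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p"])
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["q"] <= fdr
        table = table.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    else:
        table["q"] = []
        table["significant"] = []
    return table
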