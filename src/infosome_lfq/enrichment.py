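"""Over-representation analysis of a protein list against GMT gene-set collections.

The statistic is the hypergeometric upper tail: with a universe of N ids of
which K belong to a set, drawing the n-id query at random, the p-value is
P(X >= k) for the observed overlap k. Fold enrichment is (k/n)/(K/N).
Benjamini–Hochberg q-values are computed over all tested sets. The same
machinery serves GO/KEGG-style collections and miRNA→target sets alike.

The background universe defaults to the experiment's quantified/filtered
protein list rather than a whole proteome, matching standard ORA practice of
conditioning on what could have been observed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["hypergeom_test", "bh_adjust", "run_ora"]


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k) for overlap k.

    Parameters: set size ``K`` and query size ``n`` within a universe of
    ``N``; requires 0 <= k <= min(n, K) <= N.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    # sf(k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p <= 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_ora(
    query,
    collection: GeneSetCollection,
    universe=None,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Test every gene set for over-representation of the query list.

    Query ids outside the universe are dropped (count logged). Sets are
    restricted to the universe; sets with overlap below ``min_overlap`` are
    not tested. Results are sorted by p ascending with set-name tie-break.

    Returns columns: set_name, overlap_k, set_size_K, query_n, universe_N,
    fold_enrichment, p_value, q_value.
    """
    if universe is None:
        universe = collection.universe
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    q = frozenset(query)
    dropped = len(q - uni)
    if dropped:
        logger.info("dropped %d query ids outside the universe", dropped)
    q &= uni
    restricted = collection.restricted(uni)
    N, n = len(uni), len(q)
    rows = []
    for name, members in restricted.sets.items():
        K = len(members)
        k = len(q & members)
        if k < min_overlap:
            continue
        fe = (k / n) / (K / N) if n else 0.0
        rows.append((name, k, K, n, N, fe, hypergeom_test(k, K, n, N)))
    out = pd.DataFrame(
        rows,
        columns=["set_name", "overlap_k", "set_size_K", "query_n", "universe_N",
                 "fold_enrichment", "p_value"],
    )
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out
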