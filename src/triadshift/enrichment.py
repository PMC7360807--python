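"""Hypergeometric over-representation testing of gene sets.

Given a query set (e.g. the down-regulated genes), a background population
(by convention the expressed-overall genes, not the whole annotation
universe) and a flat gene-to-term annotation, each term is tested for
over-representation with the upper tail of the hypergeometric distribution,
P(X >= k) for k query hits among K annotated genes in a population of N
with a query of size n. P-values are BH-adjusted across the tested terms
only. One-sided over-representation only: depletion is not tested.
"""

from __future__ import annotations

import warnings
from typing import Collection

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import InvalidCountsError, QueryOutsidePopulationError
from .iodata import GeneSetAnnotation
from .diffexpr import bh_adjust

__all__ = ["hypergeom_upper", "enrich"]


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail P(X >= k) for hypergeometric(N, K, n).

    N: population size, K: annotated in population, n: sample (query) size,
    k: annotated in sample. Requires 0 <= k <= min(n, K) and n, K <= N.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise InvalidCountsError(
            f"invalid hypergeometric counts N={N}, K={K}, n={n}, k={k}"
        )
    p = float(hypergeom.sf(k - 1, N, K, n))
    # keep the probability in (0, 1]: the exact tail is positive whenever the
    # counts are admissible, but the survival function can underflow
    return min(max(p, np.finfo(float).tiny), 1.0)


def enrich(
    query: Collection[str],
    annotation: GeneSetAnnotation,
    population: Collection[str],
    fdr: float = 0.05,
    min_term_size: int = 5,
    max_term_size: int = 2000,
    strict: bool = True,
) -> pd.DataFrame:
    """Test every eligible term for over-representation in the query.

    Terms are restricted to the population before sizing; only terms with
    ``min_term_size <= K <= max_term_size`` are tested, and BH adjustment
    runs across exactly those terms. Query genes outside the population
    raise (strict) or are dropped with a warning (lenient).

    Returns a DataFrame sorted by raw p with columns term_id, N, K, n, k,
    pvalue, padj, significant.
    """
    query = set(query)
    population = set(population)
    if not query:
        raise InvalidCountsError("query gene set is empty")
    outside = query - population
    if outside:
        if strict:
            raise QueryOutsidePopulationError(
                f"{len(outside)} query genes outside the population, "
                f"e.g. {sorted(outside)[:5]}"
            )
        warnings.warn(
            f"dropping {len(outside)} query genes outside the population",
            stacklevel=2,
        )
        query = query - outside

    pairs = annotation.pairs
    pairs = pairs[pairs["gene_id"].isin(population)]
    K_by_term = pairs.groupby("term_id")["gene_id"].nunique()
    K_by_term = K_by_term[(K_by_term >= min_term_size) & (K_by_term <= max_term_size)]
    in_query = pairs["gene_id"].isin(query)
    k_by_term = pairs[in_query].groupby("term_id")["gene_id"].nunique()

    N, n = len(population), len(query)
    records = []
    for term, K in K_by_term.items():
        k = int(k_by_term.get(term, 0))
        records.append((term, N, int(K), n, k, hypergeom_upper(N, int(K), n, k)))
    out = pd.DataFrame(
        records, columns=["term_id", "N", "K", "n", "k", "pvalue"]
    )
    if len(out):
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
        out["significant"] = out["padj"] < fdr
        out = out.sort_values(["pvalue", "term_id"], kind="stable").reset_index(drop=True)
    else:
        out["padj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
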