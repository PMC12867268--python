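"""Hypergeometric over-representation analysis (ORA) of a query gene list.

For a term of size K in a universe of N genes and a query of size n with k
hits in the term, p = P(X >= k) for X ~ Hypergeometric(N, K, n), computed
from the exact upper tail. BH adjustment runs across terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats

from .io import ValidationError
from .twas import bh_adjust

__all__ = ["OraResult", "ora"]


@dataclass
class OraResult:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    adj_p: float
    fold_enrichment: float


def ora(
    query_genes: Iterable[str],
    term_sets: Mapping[str, tuple[str, set[str]]],
    universe: Iterable[str],
) -> tuple[list[OraResult], int]:
    """Upper-tail hypergeometric test of each term against the query.

    Query genes outside the universe are dropped and counted (second return
    value); term sets are restricted to the universe. Results are sorted by
    adj_p ascending, ties by term_id.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValidationError("empty universe")
    query = set(query_genes)
    n_outside = len(query - universe_set)
    query &= universe_set
    if not query:
        raise ValidationError("query empty after restriction to the universe")
    N = len(universe_set)
    n = len(query)
    results: list[OraResult] = []
    for term_id in sorted(term_sets):
        name, members = term_sets[term_id]
        term = members & universe_set
        K = len(term)
        if K == 0:
            continue
        k = len(term & query)
        # exact upper tail P(X >= k); sf(k-1) is the exact survival sum
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, 5e-324), 1.0)
        fold = (k / n) / (K / N)
        results.append(OraResult(term_id, name, k, K, n, N, p, 0.0, fold))
    if results:
        adj = bh_adjust([r.p for r in results])
        for r, a in zip(results, adj):
            r.adj_p = float(a)
    results.sort(key=lambda r: (r.adj_p, r.term_id))
    return results, n_outside
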