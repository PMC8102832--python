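"""Hypergeometric over-representation analysis with BH false-discovery control.

For a query of n genes drawn from a universe of N, a set with K members and
k of them in the query has one-sided enrichment p-value

    p = sum_{i=k}^{min(K,n)} C(K,i) C(N-K, n-i) / C(N,n),

the upper tail of the hypergeometric distribution. The rich ratio k/K is
reported for plotting. Significance is flagged on the raw p (<= 0.05 by
default) with BH q-values reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetCollection, harmonize_gene

__all__ = ["EnrichmentResult", "hypergeom_tail", "bh_adjust", "enrich"]


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    description: str
    overlap_count: int
    set_size: int
    query_size: int
    universe_size: int
    rich_ratio: float
    p: float
    q: float
    significant: bool
    overlap_members: frozenset[str]


def hypergeom_tail(overlap: int, set_size: int, query: int, universe: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    Evaluated through the survival function of scipy's hypergeometric
    distribution, which works in log space and is stable for large N.
    """
    if not (0 <= overlap <= min(set_size, query)):
        raise ValueError(f"impossible overlap {overlap} for K={set_size}, n={query}")
    if set_size > universe or query > universe:
        raise ValueError("set or query larger than universe")
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe, set_size, query))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    p_cut: float = 0.05,
) -> tuple[list[EnrichmentResult], int]:
    """Over-representation of ``query`` against every set in the collection.

    The query is harmonized and deduplicated; genes outside the universe are
    dropped and their count returned. Results are sorted by p then set_id.
    """
    if not collection.universe:
        raise ValueError("empty gene universe")
    q_raw = {harmonize_gene(g) for g in query}
    q_in = q_raw & collection.universe
    n_dropped = len(q_raw) - len(q_in)
    n, N = len(q_in), len(collection.universe)
    rows = []
    for sid in sorted(collection.sets):
        desc, members = collection.sets[sid]
        overlap = q_in & members
        k, K = len(overlap), len(members)
        p = hypergeom_tail(k, K, n, N)
        rows.append((sid, desc, k, K, overlap, p))
    qvals = bh_adjust([r[5] for r in rows])
    results = [
        EnrichmentResult(
            set_id=sid,
            description=desc,
            overlap_count=k,
            set_size=K,
            query_size=n,
            universe_size=N,
            rich_ratio=k / K,
            p=p,
            q=float(qv),
            significant=p <= p_cut,
            overlap_members=frozenset(overlap),
        )
        for (sid, desc, k, K, overlap, p), qv in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.set_id))
    return results, n_dropped
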