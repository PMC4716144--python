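"""Gene-set over-representation with the hybrid pathway score.

A pathway (gene set) is scored against a query list by the exact
hypergeometric upper tail P(X >= k) and the enrichment ratio
R = k / (n*K/N) (observed over expected overlap).  The two are combined
into a single hybrid index (-log10 p) * R.  A pathway is admitted only when
it overlaps the query in at least two genes and p <= 0.05 — the admission
filter of the source workflow; no multiple-testing correction is applied to
the filter (a BH column is emitted for transparency).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

from scipy.stats import hypergeom

from .diffexpr import bh_fdr
from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

P_FLOOR_DEFAULT = 1e-300


@dataclass
class EnrichmentRecord:
    set_id: str
    k: int  # overlap count
    K: int  # set size in universe
    n: int  # query size in universe
    N: int  # universe size
    p: float  # hypergeometric upper-tail probability
    bh_q: float  # BH-adjusted p over tested sets (informational)
    R: float  # enrichment ratio, observed/expected overlap
    hybrid: float  # (-log10 p) * R


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact over-representation tail P(X >= k), X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def hybrid_score(p: float, R: float) -> float:
    """(-log10 p) * R.  The caller must floor p away from zero first."""
    if p == 0:
        raise ValueError("p = 0: floor the probability before scoring")
    if not 0 < p <= 1:
        raise ValueError(f"p must lie in (0, 1], got {p}")
    if R < 0:
        raise ValueError(f"enrichment ratio must be >= 0, got {R}")
    return (-math.log10(p)) * R


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_overlap: int = 2,
    p_cut: float = 0.05,
    p_floor: float = P_FLOOR_DEFAULT,
) -> list[EnrichmentRecord]:
    """Score every gene set against the query; admit k >= min_overlap and
    p <= p_cut; sort admitted records by hybrid score descending.

    Gene identifiers are matched case-insensitively.  Query genes outside
    the universe are dropped (with a logged count); each set is intersected
    with the universe before its size K is taken.
    """
    universe_fold = {g.casefold() for g in universe}
    if not universe_fold:
        raise ValueError("empty universe")
    query_fold = {g.casefold() for g in query}
    dropped = len(query_fold - universe_fold)
    if dropped:
        logger.info("dropped %d query genes outside the universe", dropped)
    query_fold &= universe_fold
    if not query_fold:
        raise ValueError("query is empty after intersecting with the universe")

    N = len(universe_fold)
    n = len(query_fold)
    raw: list[tuple[str, int, int, float]] = []
    for sid in collection:
        members = {m.casefold() for m in collection.members(sid)} & universe_fold
        K = len(members)
        if K == 0:
            continue
        k = len(members & query_fold)
        p = hypergeom_tail(k, K, n, N)
        raw.append((sid, k, K, p))

    qvals = bh_fdr([p for (_, _, _, p) in raw]) if raw else []
    records = []
    for (sid, k, K, p), q in zip(raw, qvals):
        if k < min_overlap or p > p_cut:
            continue
        expected = n * K / N
        R = k / expected if expected > 0 else 0.0
        records.append(
            EnrichmentRecord(
                set_id=sid, k=k, K=K, n=n, N=N,
                p=p, bh_q=q, R=R, hybrid=hybrid_score(max(p, p_floor), R),
            )
        )
    records.sort(key=lambda r: (-r.hybrid, r.set_id))
    return records
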