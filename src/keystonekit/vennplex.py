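"""Polarity-aware multi-list Venn partitioning.

Given 2-6 per-condition gene lists that carry signed scores (z-ratios, with
sign encoding regulation polarity), decompose the union into the exact
2^n - 1 Venn sectors, split each multi-list sector by its per-list sign
pattern, and flag contra-regulated genes: genes present in at least two
lists with at least one sign disagreement.  Gene identifiers are matched
case-insensitively across lists; case-fold collisions are reported, never
silently merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

MAX_LISTS = 6


@dataclass
class SignedGeneList:
    """A condition/timepoint label plus gene -> signed score entries."""

    list_id: str
    entries: dict[str, float]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"list {self.list_id!r} is empty")
        for gene, score in self.entries.items():
            if score == 0:
                raise ValueError(
                    f"list {self.list_id!r}: gene {gene!r} has zero score "
                    "(zero polarity is undefined)"
                )
        folded: dict[str, str] = {}
        for gene in self.entries:
            key = gene.casefold()
            if key in folded:
                raise ValueError(
                    f"list {self.list_id!r}: {gene!r} collides with "
                    f"{folded[key]!r} after case-folding"
                )
            folded[key] = gene

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class VennPartition:
    lists: list[SignedGeneList]
    # sector key: frozenset of list_ids -> canonical gene ids
    sectors: dict[frozenset, list[str]]
    # sector -> sign pattern (tuple of +1/-1 in sorted-list_id order) -> genes
    polarity_sectors: dict[frozenset, dict[tuple, list[str]]]
    contra: set[str]
    # case-fold collisions observed across lists: canonical -> variant spellings
    collisions: dict[str, list[str]] = field(default_factory=dict)

    def list_ids(self) -> list[str]:
        return [sl.list_id for sl in self.lists]

    def sector(self, *list_ids: str) -> list[str]:
        return self.sectors.get(frozenset(list_ids), [])

    def union_size(self) -> int:
        return sum(len(v) for v in self.sectors.values())

    def sector_counts(self, separate_contra: bool = False) -> dict[frozenset, int]:
        """Sector sizes; with ``separate_contra`` contra-regulated genes are
        tallied apart from their sector (both conventions are offered because
        the original tool's figure convention is ambiguous)."""
        if not separate_contra:
            return {k: len(v) for k, v in self.sectors.items()}
        return {
            k: sum(1 for g in v if g not in self.contra)
            for k, v in self.sectors.items()
        }


def partition(lists: Iterable[SignedGeneList]) -> VennPartition:
    """Exact set-algebra partition of >=2 signed gene lists."""
    lists = list(lists)
    if len(lists) < 2:
        raise ValueError("need at least 2 lists")
    if len(lists) > MAX_LISTS:
        raise ValueError(f"at most {MAX_LISTS} lists supported")
    ids = [sl.list_id for sl in lists]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate list_id")

    # canonical id: first-seen spelling of the case-folded key
    canonical: dict[str, str] = {}
    collisions: dict[str, set[str]] = {}
    membership: dict[str, dict[str, float]] = {}  # canon -> list_id -> score
    for sl in lists:
        for gene, score in sl.entries.items():
            key = gene.casefold()
            canon = canonical.setdefault(key, gene)
            if gene != canon:
                collisions.setdefault(canon, {canon}).add(gene)
            membership.setdefault(canon, {})[sl.list_id] = score

    sectors: dict[frozenset, list[str]] = {}
    polarity: dict[frozenset, dict[tuple, list[str]]] = {}
    contra: set[str] = set()
    for canon, present in membership.items():
        sector = frozenset(present)
        sectors.setdefault(sector, []).append(canon)
        pattern = tuple(
            1 if present[lid] > 0 else -1 for lid in sorted(present)
        )
        polarity.setdefault(sector, {}).setdefault(pattern, []).append(canon)
        if len(present) >= 2 and len({s > 0 for s in present.values()}) > 1:
            contra.add(canon)

    return VennPartition(
        lists=lists,
        sectors={k: sorted(v) for k, v in sectors.items()},
        polarity_sectors={
            k: {p: sorted(g) for p, g in pats.items()} for k, pats in polarity.items()
        },
        contra=contra,
        collisions={k: sorted(v) for k, v in collisions.items()},
    )


def uniqueness_fraction(p: VennPartition, list_id: str) -> float:
    """Percentage of a list's genes unique to it (its singleton sector),
    reported to 2 decimal places."""
    match = [sl for sl in p.lists if sl.list_id == list_id]
    if not match:
        raise ValueError(f"unknown list_id {list_id!r}")
    singleton = p.sectors.get(frozenset([list_id]), [])
    return round(100.0 * len(singleton) / len(match[0]), 2)


def common_to_at_least(p: VennPartition, k: int) -> set[str]:
    """Union of sectors spanning at least k lists."""
    n = len(p.lists)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    out: set[str] = set()
    for sector, genes in p.sectors.items():
        if len(sector) >= k:
            out.update(genes)
    return out
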