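"""Overlap analysis between predicted secretomes.

Similarity is reported relative to a *reference* set: the percentage is
100 x |intersection| / |reference|, deliberately asymmetric (comparing a
small granule secretome against a whole-islet secretome asks how much of
the former is contained in the latter). Venn region counts give the full
disjoint decomposition for two or three sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .errors import ConfigurationError
from .records import SecretomeSet, round_half_up


@dataclass(frozen=True)
class OverlapReport:
    reference_id: str
    other_id: str
    n_reference: int
    n_other: int
    n_intersection: int

    @property
    def pct_of_reference(self) -> float:
        return (
            100.0 * self.n_intersection / self.n_reference if self.n_reference else 0.0
        )

    @property
    def pct_of_reference_rounded(self) -> float:
        return round_half_up(self.pct_of_reference, 1)


@dataclass
class VennCounts:
    """Disjoint region counts for 2-3 sets, keyed by the frozenset of the
    set ids that a region belongs to (exclusively)."""

    set_ids: tuple[str, ...]
    region_counts: dict[frozenset[str], int]

    @property
    def n_union(self) -> int:
        return sum(self.region_counts.values())

    def count(self, *ids: str) -> int:
        return self.region_counts[frozenset(ids)]

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(sorted(region)), "count": count}
            for region, count in sorted(
                self.region_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["region", "count"])


def _check_strategies(sets: tuple[SecretomeSet, ...]) -> None:
    strategies = {s.key_strategy for s in sets}
    if len(strategies) > 1:
        raise ConfigurationError(
            f"cannot compare sets built with different key strategies: {sorted(strategies)}"
        )


def overlap(reference: SecretomeSet, other: SecretomeSet) -> OverlapReport:
    """Exact key intersection with the percentage relative to ``reference``."""
    _check_strategies((reference, other))
    intersection = reference.keys & other.keys
    return OverlapReport(
        reference_id=reference.dataset_id,
        other_id=other.dataset_id,
        n_reference=len(reference),
        n_other=len(other),
        n_intersection=len(intersection),
    )


def venn(sets: list[SecretomeSet]) -> VennCounts:
    """Disjoint region counts for two or three secretome sets.

    Regions are exclusive: a key counts toward exactly one region (the one
    matching the precise subset of sets containing it), so the counts sum
    to the size of the union.
    """
    if not 2 <= len(sets) <= 3:
        raise ConfigurationError(f"venn requires 2 or 3 sets, got {len(sets)}")
    ids = tuple(s.dataset_id for s in sets)
    if len(set(ids)) != len(ids):
        raise ConfigurationError("venn requires distinct dataset ids")
    _check_strategies(tuple(sets))

    by_id = {s.dataset_id: s.keys for s in sets}
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(ids) + 1):
        for members in combinations(ids, r):
            inside = set.intersection(*(set(by_id[i]) for i in members))
            outside = set.union(
                set(), *(by_id[i] for i in ids if i not in members)
            )
            regions[frozenset(members)] = len(inside - outside)
    return VennCounts(set_ids=ids, region_counts=regions)
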