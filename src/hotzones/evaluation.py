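"""Comparing zone sets against annotations and across samples.

Overlap everywhere means sharing at least one base (matching the merging
rule used to build zones); there is no minimum-fraction option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Union

from intervaltree import IntervalTree

from .regions import BindingRegion, RegionSet
from .zones import DenseZone, ZoneSet

IntervalCollection = Union[RegionSet, ZoneSet]

__all__ = [
    "OverlapSummary",
    "overlap_summary",
    "method_concordance",
    "conserved_exclusive",
]


@dataclass(frozen=True)
class OverlapSummary:
    """Two-directional any-overlap counts between zones and features."""

    n_zones: int
    n_features: int
    zones_hitting_features: int
    features_hitting_zones: int

    @property
    def zones_fraction(self) -> float:
        return self.zones_hitting_features / self.n_zones if self.n_zones else 0.0

    @property
    def features_fraction(self) -> float:
        return self.features_hitting_zones / self.n_features if self.n_features else 0.0

    def to_dict(self) -> dict:
        return {
            "n_zones": self.n_zones,
            "n_features": self.n_features,
            "zones_hitting_features": self.zones_hitting_features,
            "zones_fraction": self.zones_fraction,
            "features_hitting_zones": self.features_hitting_zones,
            "features_fraction": self.features_fraction,
        }


def _intervals(collection: IntervalCollection) -> list[tuple[str, int, int]]:
    out = []
    for item in collection:
        if isinstance(item, (BindingRegion, DenseZone)):
            out.append((item.chrom, item.start, item.end))
        else:  # pragma: no cover - defensive
            raise TypeError(f"unsupported element {type(item)!r}")
    return out


def _trees(collection: IntervalCollection) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees; inclusive [s, e] stored half-open."""
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in _intervals(collection):
        trees.setdefault(chrom, IntervalTree()).addi(s, e + 1)
    return trees


def _count_hitting(items: IntervalCollection, other: IntervalCollection) -> int:
    trees = _trees(other)
    n = 0
    for chrom, s, e in _intervals(items):
        tree = trees.get(chrom)
        if tree is not None and tree.overlaps(s, e + 1):
            n += 1
    return n


def overlap_summary(zones: ZoneSet, features: IntervalCollection) -> OverlapSummary:
    """Count zones hitting >= 1 feature and features hitting >= 1 zone.

    A "hit" is a shared base in 1-based inclusive coordinates; every
    element is counted at most once regardless of how many partners it
    touches. Empty inputs yield zero counts and fraction 0 by convention.
    """
    return OverlapSummary(
        n_zones=len(zones),
        n_features=len(features),
        zones_hitting_features=_count_hitting(zones, features),
        features_hitting_zones=_count_hitting(features, zones),
    )


def method_concordance(zones_a: ZoneSet, zones_b: ZoneSet) -> float:
    """Fraction of zones in A intersecting at least one zone of B.

    Returns NaN when A is empty (the fraction is undefined).
    """
    if len(zones_a) == 0:
        return math.nan
    return _count_hitting(zones_a, zones_b) / len(zones_a)


def conserved_exclusive(
    zone_sets: Mapping[str, ZoneSet],
) -> dict[str, dict[str, object]]:
    """Partition each sample's zones into conserved / exclusive / other.

    For each named sample, a zone is *conserved* when it overlaps (even
    partially) at least one zone in **every** other sample, *exclusive*
    when it overlaps none, and *other* in between. Requires >= 2 samples.

    Returns
    -------
    dict mapping sample name to a record with the three ZoneSets plus
    per-category counts and fractions.
    """
    if len(zone_sets) < 2:
        raise ValueError("conserved/exclusive comparison requires >= 2 samples")
    names = list(zone_sets)
    trees = {name: _trees(zone_sets[name]) for name in names}
    result: dict[str, dict[str, object]] = {}
    for name in names:
        others = [n for n in names if n != name]
        conserved, exclusive, other = [], [], []
        for z in zone_sets[name]:
            hits = 0
            for o in others:
                tree = trees[o].get(z.chrom)
                if tree is not None and tree.overlaps(z.start, z.end + 1):
                    hits += 1
            if hits == len(others):
                conserved.append(z)
            elif hits == 0:
                exclusive.append(z)
            else:
                other.append(z)
        total = len(zone_sets[name])
        zs = zone_sets[name]
        result[name] = {
            "conserved": ZoneSet(conserved, zs.method, zs.acc_type, zs.w),
            "exclusive": ZoneSet(exclusive, zs.method, zs.acc_type, zs.w),
            "other": ZoneSet(other, zs.method, zs.acc_type, zs.w),
            "n_total": total,
            "n_conserved": len(conserved),
            "n_exclusive": len(exclusive),
            "n_other": len(other),
            "fraction_conserved": len(conserved) / total if total else 0.0,
            "fraction_exclusive": len(exclusive) / total if total else 0.0,
        }
    return result
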