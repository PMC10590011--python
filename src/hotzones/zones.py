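"""Dense-zone extraction and HOT-zone selection.

Two alternative search methods produce scored candidate ("dense") zones:

*binding region*
    input regions sharing at least one base are transitively merged into
    maximal zones; each zone's accumulation index is the number of
    distinct TFs binding at least one base of it. The moving window is
    never applied here — merging acts on the original regions.
*overlap*
    every maximal run of contiguous bases sharing one non-zero
    accumulation value becomes a zone, and the run value is inherited as
    its accumulation index. Works for any accumulation type and window.

A thresholding step then promotes dense zones with index >= threshold to
HOT zones. The threshold is data driven: *top k percentage* (minimum index
among the top k% of zones sorted by index) or *over k standard deviations*
(ceiling of mean + k * sd of the per-base accumulation over non-zero
bases), or a user-supplied absolute integer.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .accumulation import (
    AccumulationStats,
    AccumulationTrack,
    accumulation_stats,
    compute_accumulation,
)
from .regions import RegionSet

__all__ = [
    "DenseZone",
    "ZoneSet",
    "ThresholdSpec",
    "ThresholdResult",
    "binding_region_zones",
    "overlap_zones",
    "resolve_threshold",
    "select_hot",
    "find_hot_zones",
]


@dataclass(frozen=True, order=True)
class DenseZone:
    """A scored candidate zone, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    index: int
    method: str = "overlap"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.index < 1:
            raise ValueError(f"accumulation index must be >= 1, got {self.index}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def intersects(self, other: "DenseZone") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and self.end >= other.start
        )


class ZoneSet:
    """A sorted collection of dense (or HOT) zones with length statistics.

    Zones produced by one method on one dataset never overlap each other;
    ``length_stats`` reports min/max/mean/median/sd of the zone lengths
    (sample sd, NaN for fewer than two zones; the median of an even count
    is the mean of the two central values).
    """

    def __init__(
        self,
        zones: Iterable[DenseZone],
        method: str = "overlap",
        acc_type: str | None = None,
        w: int | None = None,
    ):
        self.zones: tuple[DenseZone, ...] = tuple(
            sorted(zones, key=lambda z: (z.chrom, z.start, z.end))
        )
        self.method = method
        self.acc_type = acc_type
        self.w = w

    def __len__(self) -> int:
        return len(self.zones)

    def __iter__(self) -> Iterator[DenseZone]:
        return iter(self.zones)

    def __getitem__(self, i: int) -> DenseZone:
        return self.zones[i]

    def __repr__(self) -> str:
        return f"ZoneSet(n={len(self.zones)}, method={self.method!r})"

    @property
    def length_stats(self) -> dict[str, float]:
        lengths = [z.length for z in self.zones]
        if not lengths:
            return {"n": 0, "min": math.nan, "max": math.nan, "mean": math.nan,
                    "median": math.nan, "sd": math.nan}
        sd = statistics.stdev(lengths) if len(lengths) > 1 else math.nan
        return {
            "n": len(lengths),
            "min": float(min(lengths)),
            "max": float(max(lengths)),
            "mean": statistics.fmean(lengths),
            "median": float(statistics.median(lengths)),
            "sd": sd,
        }

    def by_chrom(self, chrom: str) -> tuple[DenseZone, ...]:
        return tuple(z for z in self.zones if z.chrom == chrom)

    def total_span(self) -> int:
        """Total number of bases covered by the zones."""
        return sum(z.length for z in self.zones)

    def summary(self, threshold: "ThresholdResult | None" = None) -> dict:
        """JSON-serializable record: method, parameters, counts, length
        statistics and (if given) the resolved threshold."""
        ls = self.length_stats
        out = {
            "method": self.method,
            "acc_type": self.acc_type,
            "w": self.w,
            "n_zones": len(self.zones),
            "total_span_bases": self.total_span(),
            "length_stats": {k: (None if isinstance(v, float) and math.isnan(v) else v)
                             for k, v in ls.items()},
        }
        if threshold is not None:
            out["threshold"] = threshold.to_dict()
        return out


@dataclass(frozen=True)
class ThresholdSpec:
    """Which thresholding procedure to apply and its k parameter.

    procedure : {"top_k_pct", "k_std", "absolute"}
        ``top_k_pct``: k is a percentage in (0, 100]; ``k_std``: k >= 0
        standard deviations; ``absolute``: k is the threshold itself
        (integer >= 1).
    """

    procedure: str
    k: float

    def __post_init__(self) -> None:
        if self.procedure not in {"top_k_pct", "k_std", "absolute"}:
            raise ValueError(f"unknown threshold procedure {self.procedure!r}")
        if self.procedure == "top_k_pct" and not 0 < self.k <= 100:
            raise ValueError(f"top_k_pct requires 0 < k <= 100, got {self.k}")
        if self.procedure == "k_std" and self.k < 0:
            raise ValueError(f"k_std requires k >= 0, got {self.k}")
        if self.procedure == "absolute" and (self.k < 1 or self.k != int(self.k)):
            raise ValueError(f"absolute requires an integer k >= 1, got {self.k}")


@dataclass(frozen=True)
class ThresholdResult:
    """A resolved integer threshold plus the inputs it was derived from."""

    threshold: int
    procedure: str
    k: float
    derived_from: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "procedure": self.procedure,
            "k": self.k,
            "derived_from": self.derived_from,
        }


def binding_region_zones(regions: RegionSet, chroms: Sequence[str] | None = None) -> ZoneSet:
    """Merge overlapping input regions into dense zones scored by TF count.

    Regions sharing >= 1 base are transitively combined into one maximal
    zone (book-ended regions — end + 1 == next start — stay separate); the
    zone's accumulation index is the number of distinct TFs having at
    least one region inside it. No moving window is applied.
    """
    todo = sorted(regions.chromosomes) if chroms is None else list(chroms)
    zones: list[DenseZone] = []
    for chrom in todo:
        rs = regions.by_chrom(chrom)  # already sorted by start
        if not rs:
            continue
        cur_start, cur_end = rs[0].start, rs[0].end
        cur_tfs = {rs[0].tf}
        for r in rs[1:]:
            if r.start <= cur_end:  # shared base
                cur_end = max(cur_end, r.end)
                cur_tfs.add(r.tf)
            else:
                zones.append(DenseZone(chrom, cur_start, cur_end, len(cur_tfs), "binding_region"))
                cur_start, cur_end, cur_tfs = r.start, r.end, {r.tf}
        zones.append(DenseZone(chrom, cur_start, cur_end, len(cur_tfs), "binding_region"))
    return ZoneSet(zones, method="binding_region")


def overlap_zones(tracks: Mapping[str, AccumulationTrack] | Iterable[AccumulationTrack]) -> ZoneSet:
    """One dense zone per maximal non-zero constant run of the track(s)."""
    if isinstance(tracks, Mapping):
        tracks = tracks.values()
    tracks = list(tracks)
    zones = [
        DenseZone(t.chrom, s, e, v, "overlap")
        for t in tracks
        for s, e, v in t.segments()
    ]
    acc_type = tracks[0].acc_type if tracks else None
    w = tracks[0].w if tracks else None
    return ZoneSet(zones, method="overlap", acc_type=acc_type, w=w)


def resolve_threshold(
    spec: ThresholdSpec,
    zones: ZoneSet | None = None,
    stats: AccumulationStats | None = None,
) -> ThresholdResult:
    """Resolve a ThresholdSpec into a concrete integer threshold.

    ``top_k_pct`` sorts zones by index descending, takes the top
    m = ceil(k/100 * N) zones and returns the minimum index among them.
    ``k_std`` returns ceil(mean + k * sd) of the per-base accumulation
    over non-zero bases. ``absolute`` returns k unchanged.
    """
    if spec.procedure == "absolute":
        return ThresholdResult(int(spec.k), "absolute", spec.k)
    if spec.procedure == "top_k_pct":
        if zones is None or len(zones) == 0:
            raise ValueError("top_k_pct thresholding requires a non-empty zone set")
        idx = sorted((z.index for z in zones), reverse=True)
        m = math.ceil(spec.k / 100 * len(idx))
        thr = idx[m - 1]
        return ThresholdResult(
            thr, "top_k_pct", spec.k,
            {"n_zones": len(idx), "n_top": m, "max_index": idx[0]},
        )
    # k_std
    if stats is None or stats.is_degenerate:
        raise ValueError(
            "k_std thresholding requires accumulation statistics over at "
            "least one non-zero base"
        )
    thr = math.ceil(stats.mean + spec.k * stats.sd)
    return ThresholdResult(
        max(thr, 1), "k_std", spec.k,
        {"mean": stats.mean, "sd": stats.sd, "n_nonzero_bases": stats.n_nonzero_bases},
    )


def select_hot(zones: ZoneSet, threshold: ThresholdResult) -> ZoneSet:
    """HOT zones: all dense zones with index >= threshold (ties included)."""
    if threshold.threshold < 1:
        raise ValueError("resolved threshold must be >= 1")
    hot = [z for z in zones if z.index >= threshold.threshold]
    return ZoneSet(hot, method=zones.method, acc_type=zones.acc_type, w=zones.w)


def find_hot_zones(
    regions: RegionSet,
    method: str = "overlap",
    acc_type: str = "tf",
    w: int = 0,
    spec: ThresholdSpec = ThresholdSpec("top_k_pct", 1.0),
    chroms: Sequence[str] | None = None,
    per_chromosome: bool = False,
) -> tuple[ZoneSet, ZoneSet, ThresholdResult] | dict[str, tuple[ZoneSet, ZoneSet, ThresholdResult]]:
    """Run the full dense-zone + HOT-zone pipeline.

    For the ``overlap`` method the dense zones are the constant runs of
    the (acc_type, w) accumulation track. For the ``binding_region``
    method the dense zones come from merging the raw input regions; when
    ``k_std`` thresholding is requested, its per-base statistics are taken
    from the TF-accumulation track at the same `w`.

    By default zones and base statistics are pooled genome wide for
    thresholding; with ``per_chromosome=True`` each chromosome is
    thresholded independently and a dict keyed by chromosome is returned.

    Returns
    -------
    (dense ZoneSet, HOT ZoneSet, ThresholdResult), or a dict of such
    triples when ``per_chromosome`` is set.
    """
    if method not in {"binding_region", "overlap"}:
        raise ValueError(f"method must be binding_region or overlap, got {method!r}")

    if per_chromosome:
        todo = sorted(regions.chromosomes) if chroms is None else list(chroms)
        return {
            c: find_hot_zones(regions, method, acc_type, w, spec, chroms=[c])
            for c in todo
        }

    if method == "overlap":
        tracks = compute_accumulation(regions, acc_type, w, chroms)
        dense = overlap_zones(tracks)
        dense = ZoneSet(dense.zones, method="overlap", acc_type=acc_type, w=w)
        stats = accumulation_stats(tracks) if spec.procedure == "k_std" else None
    else:
        dense = binding_region_zones(regions, chroms)
        dense = ZoneSet(dense.zones, method="binding_region", acc_type=acc_type, w=w)
        stats = None
        if spec.procedure == "k_std":
            stats = accumulation_stats(compute_accumulation(regions, "tf", w, chroms))
    if len(dense) == 0:
        # empty input (e.g. after a chromosome filter): empty outputs
        fallback = int(spec.k) if spec.procedure == "absolute" else 1
        threshold = ThresholdResult(fallback, spec.procedure, spec.k,
                                    {"note": "empty input"})
        return dense, select_hot(dense, threshold), threshold
    threshold = resolve_threshold(spec, zones=dense, stats=stats)
    hot = select_hot(dense, threshold)
    return dense, hot, threshold
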