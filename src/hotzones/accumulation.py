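"""Per-base TF-binding accumulation tracks.

The accumulation vector assigns every DNA base ``b`` a non-negative integer
under one of three quantification strategies, optionally smoothed by a
symmetric moving window of semi-width ``w`` (the neighborhood
``[max(1, b - w), b + w]``):

``tf``
    number of **distinct TFs** with at least one binding region
    intersecting the neighborhood of ``b``;
``region``
    number of **input binding regions** (same-TF duplicates counted
    separately) intersecting the neighborhood;
``base``
    total number of **region bases** falling inside the neighborhood,
    i.e. the sum over regions of the intersection length.

Tracks are represented exactly as run-length-encoded segments
(start, end, value), 1-based inclusive, with zeros implicit. The tf and
region tracks are piecewise constant between interval events; the base
track is piecewise linear between events and is materialized into maximal
constant runs (a ramp contributes one run per base). No floating point
enters the computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .regions import BindingRegion, RegionSet

ACC_TYPES = ("tf", "region", "base")

__all__ = [
    "AccumulationTrack",
    "AccumulationStats",
    "ACC_TYPES",
    "compute_accumulation",
    "accumulation_stats",
    "write_bedgraph",
    "write_wiggle",
]


@dataclass(frozen=True)
class AccumulationTrack:
    """Run-length-encoded accumulation vector for one chromosome.

    ``starts``/``ends``/``values`` are parallel arrays of maximal constant
    runs, sorted, non-overlapping and canonical: adjacent runs
    (``ends[i] + 1 == starts[i+1]``) always carry different values, and all
    stored values are >= 1 (zero is implicit everywhere else).
    """

    chrom: str
    acc_type: str
    w: int
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        for name in ("starts", "ends", "values"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            object.__setattr__(self, name, arr)

    @property
    def n_segments(self) -> int:
        return len(self.starts)

    @property
    def is_empty(self) -> bool:
        return len(self.starts) == 0

    @property
    def n_nonzero_bases(self) -> int:
        return int((self.ends - self.starts + 1).sum())

    @property
    def max_value(self) -> int:
        return int(self.values.max()) if len(self.values) else 0

    @property
    def support(self) -> tuple[int, int] | None:
        """(first, last) base with non-zero value, or None if empty."""
        if self.is_empty:
            return None
        return int(self.starts[0]), int(self.ends[-1])

    def segments(self) -> Iterator[tuple[int, int, int]]:
        """Yield (start, end, value) runs in order."""
        for s, e, v in zip(self.starts, self.ends, self.values):
            yield int(s), int(e), int(v)

    def value_at(self, b: int) -> int:
        """Accumulation value at base ``b`` (0 outside all runs)."""
        if b < 1 or self.is_empty:
            return 0
        i = int(np.searchsorted(self.starts, b, side="right")) - 1
        if i >= 0 and self.ends[i] >= b:
            return int(self.values[i])
        return 0

    def to_array(self, start: int, end: int) -> np.ndarray:
        """Dense per-base vector over [start, end] (1-based inclusive)."""
        if start < 1 or start > end:
            raise ValueError("need 1 <= start <= end")
        out = np.zeros(end - start + 1, dtype=np.int64)
        for s, e, v in self.segments():
            lo, hi = max(s, start), min(e, end)
            if lo <= hi:
                out[lo - start : hi - start + 1] = v
        return out


@dataclass(frozen=True)
class AccumulationStats:
    """Distribution of accumulation values over bases with non-zero value.

    ``mean`` and ``sd`` are NaN when ``n_nonzero_bases == 0`` (callers must
    check before thresholding); ``sd`` uses the sample (n - 1) convention
    and is 0.0 for a single base.
    """

    n_nonzero_bases: int
    mean: float
    sd: float
    max_value: int

    @property
    def is_degenerate(self) -> bool:
        return self.n_nonzero_bases == 0


def _canonical(bounds: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Turn half-open runs [bounds[i], bounds[i+1]) with values[i] into
    canonical 1-based inclusive non-zero runs."""
    keep = values != 0
    if not keep.any():
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), empty.copy()
    starts = bounds[:-1][keep]
    ends = bounds[1:][keep] - 1
    vals = values[keep]
    # merge adjacent equal-valued runs
    if len(starts) > 1:
        new = np.ones(len(starts), dtype=bool)
        new[1:] = (starts[1:] != ends[:-1] + 1) | (vals[1:] != vals[:-1])
        idx = np.flatnonzero(new)
        starts = starts[idx]
        vals = vals[idx]
        ends = ends[np.append(idx[1:] - 1, len(ends) - 1)]
    return starts, ends, vals


def _runs_from_intervals(intervals: Sequence[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coverage runs (how many intervals cover each base) via event sweep."""
    if not intervals:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), empty.copy()
    arr = np.asarray(intervals, dtype=np.int64)
    events = np.concatenate([arr[:, 0], arr[:, 1] + 1])
    deltas = np.concatenate([np.ones(len(arr), dtype=np.int64),
                             -np.ones(len(arr), dtype=np.int64)])
    order = np.argsort(events, kind="stable")
    events, deltas = events[order], deltas[order]
    bounds, first = np.unique(events, return_index=True)
    # depth within [bounds[i], bounds[i+1]) = cumulative delta through all
    # events at bounds[i]; depth after the final event is always 0
    csum = np.cumsum(deltas)
    depth_at = csum[np.append(first[1:] - 1, len(csum) - 1)]
    return _canonical(bounds, depth_at[:-1])


def _merge_union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of inclusive intervals; touching intervals merge (coverage)."""
    if not intervals:
        return []
    intervals.sort()
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _expand(regions: Iterable[BindingRegion], w: int) -> list[tuple[int, int]]:
    return [(max(1, r.start - w), r.end + w) for r in regions]


def _base_track_runs(regions: Sequence[BindingRegion], w: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact runs of GB_acc(b) = sum_r |r ∩ [max(1, b-w), b+w]|.

    Uses the prefix sum C(x) = sum_r |r ∩ [1, x]| of the raw coverage
    track: for b - w >= 1 the value is C(b+w) - C(b-w-1). C is piecewise
    linear with slope = coverage, so the value as a function of b is
    piecewise linear with breakpoints where b+w or b-w-1 crosses a
    coverage-run boundary; ramps are materialized base by base.
    """
    cov_s, cov_e, cov_v = _runs_from_intervals([(r.start, r.end) for r in regions])
    if len(cov_s) == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), empty.copy()

    # prefix sums of coverage at run boundaries: C(x) for arbitrary x
    seg_len = cov_e - cov_s + 1
    cum = np.concatenate([[0], np.cumsum(seg_len * cov_v)])

    def C(x: np.ndarray) -> np.ndarray:
        """Vectorized C(x); x may be any integer array (C(x<=0) = 0)."""
        x = np.asarray(x, dtype=np.int64)
        out = np.zeros(len(x), dtype=np.int64)
        # run i covers [cov_s[i], cov_e[i]]; find last run starting <= x
        i = np.searchsorted(cov_s, x, side="right") - 1
        inside = i >= 0
        ii = np.clip(i, 0, None)
        # contribution of full runs before run i, plus partial run i
        partial = np.minimum(x, cov_e[ii]) - cov_s[ii] + 1
        partial = np.clip(partial, 0, None)
        out[inside] = cum[ii[inside]] + partial[inside] * cov_v[ii[inside]]
        return out

    lo = max(1, int(cov_s[0]) - w)
    hi = int(cov_e[-1]) + w
    if w == 0:
        return cov_s, cov_e, cov_v

    # slope of value(b) changes where b+w or b-w-1 crosses a coverage-run
    # boundary, and where the max(1, b-w) clamp releases; superfluous
    # candidates are harmless (pieces stay linear within)
    bps: set[int] = {lo, hi + 1}
    for x in np.concatenate([cov_s, cov_e + 1]):
        for b in (int(x) - w - 1, int(x) - w, int(x) + w, int(x) + w + 1):
            if lo < b <= hi:
                bps.add(b)
    for b in (w, w + 1):  # clamp boundary
        if lo < b <= hi:
            bps.add(b)
    bounds = np.array(sorted(bps), dtype=np.int64)
    piece_lo = bounds[:-1]
    piece_hi = bounds[1:] - 1

    def value(b: np.ndarray) -> np.ndarray:
        b = np.asarray(b, dtype=np.int64)
        return C(b + w) - C(np.maximum(b - w, 1) - 1)

    v_lo = value(piece_lo)
    v_hi = value(piece_hi)

    starts_out: list[np.ndarray] = []
    ends_out: list[np.ndarray] = []
    vals_out: list[np.ndarray] = []
    for a, b, va, vb in zip(piece_lo, piece_hi, v_lo, v_hi):
        n = b - a + 1
        if va == vb:  # constant piece
            starts_out.append(np.array([a]))
            ends_out.append(np.array([b]))
            vals_out.append(np.array([va]))
        else:  # linear ramp: one run per base
            if (vb - va) % (n - 1) != 0:
                raise AssertionError("non-linear piece in base track")
            step = (vb - va) // (n - 1)
            if n >= 3:  # integer-exact collinearity check at the midpoint
                mid = a + (n - 1) // 2
                if int(value(np.array([mid]))[0]) != va + step * (mid - a):
                    raise AssertionError("non-linear piece in base track")
            pos = np.arange(a, b + 1, dtype=np.int64)
            starts_out.append(pos)
            ends_out.append(pos)
            vals_out.append(va + step * (pos - a))
    starts = np.concatenate(starts_out)
    ends = np.concatenate(ends_out)
    vals = np.concatenate(vals_out)
    # re-canonicalize across piece boundaries and drop zeros
    bounds2 = np.append(starts, ends[-1] + 1)
    return _canonical(bounds2, vals)


def compute_accumulation(
    regions: RegionSet,
    acc_type: str = "tf",
    w: int = 0,
    chroms: Sequence[str] | None = None,
) -> dict[str, AccumulationTrack]:
    """Compute the accumulation track for every (requested) chromosome.

    Parameters
    ----------
    regions : RegionSet
        Input binding regions (1-based inclusive).
    acc_type : {"tf", "region", "base"}
        Quantification strategy (see module docstring).
    w : int
        Moving-window semi-width in bases, >= 0. The neighborhood of base
        ``b`` is ``[max(1, b - w), b + w]``; 1000 is the suggested value
        for smoothing real ChIP-seq data, 0 disables the window.
    chroms : sequence of str, optional
        Restrict the computation to these chromosomes.

    Returns
    -------
    dict mapping chromosome name -> :class:`AccumulationTrack`
        An empty chromosome yields an empty track, not an error.
    """
    if acc_type not in ACC_TYPES:
        raise ValueError(f"acc_type must be one of {ACC_TYPES}, got {acc_type!r}")
    if w < 0:
        raise ValueError(f"w must be >= 0, got {w}")
    todo = sorted(regions.chromosomes) if chroms is None else list(chroms)
    tracks: dict[str, AccumulationTrack] = {}
    for chrom in todo:
        rs = regions.by_chrom(chrom)
        if acc_type == "region":
            s, e, v = _runs_from_intervals(_expand(rs, w))
        elif acc_type == "tf":
            per_tf: dict[str, list[tuple[int, int]]] = {}
            for r in rs:
                per_tf.setdefault(r.tf, []).append((max(1, r.start - w), r.end + w))
            merged = [iv for tf_ivs in per_tf.values() for iv in _merge_union(tf_ivs)]
            s, e, v = _runs_from_intervals(merged)
        else:
            s, e, v = _base_track_runs(rs, w)
        tracks[chrom] = AccumulationTrack(chrom, acc_type, w, s, e, v)
    return tracks


def accumulation_stats(tracks: Iterable[AccumulationTrack] | dict) -> AccumulationStats:
    """Pooled statistics of accumulation values over all non-zero bases.

    Every base with non-zero value, on every supplied track, is weighted
    once; the standard deviation uses the sample (n - 1) convention. Base
    counts come from exact segment lengths — no per-base materialization.
    """
    if isinstance(tracks, dict):
        tracks = tracks.values()
    n = 0
    s1 = 0  # sum of values
    s2 = 0  # sum of squared values
    max_v = 0
    for t in tracks:
        lengths = (t.ends - t.starts + 1).astype(object)
        vals = t.values.astype(object)
        n += int(sum(lengths))
        s1 += int(sum(lengths * vals))
        s2 += int(sum(lengths * vals * vals))
        max_v = max(max_v, t.max_value)
    if n == 0:
        return AccumulationStats(0, math.nan, math.nan, 0)
    mean = s1 / n
    if n == 1:
        sd = 0.0
    else:
        var = (s2 - n * mean * mean) / (n - 1)
        sd = math.sqrt(max(var, 0.0))
    return AccumulationStats(n, mean, sd, max_v)


def write_bedgraph(tracks: dict[str, AccumulationTrack], path: str | Path) -> Path:
    """Export tracks as bedGraph (0-based half-open, one line per run)."""
    path = Path(path)
    with path.open("w") as fh:
        for chrom in sorted(tracks):
            for s, e, v in tracks[chrom].segments():
                fh.write(f"{chrom}\t{s - 1}\t{e}\t{v}\n")
    return path


def write_wiggle(tracks: dict[str, AccumulationTrack], path: str | Path) -> Path:
    """Export tracks in fixed-resolution wiggle format (1-based)."""
    path = Path(path)
    with path.open("w") as fh:
        for chrom in sorted(tracks):
            for s, e, v in tracks[chrom].segments():
                fh.write(f"fixedStep chrom={chrom} start={s} step=1 span=1\n")
                for _ in range(e - s + 1):
                    fh.write(f"{v}\n")
    return path
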