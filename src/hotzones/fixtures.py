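"""Synthetic binding-region datasets and the brute-force accumulation oracle.

Provides three things every stage of the pipeline can be tested against
without any download: a fixed ten-region, three-TF worked-example dataset
whose accumulation values are known by hand; a seeded random generator of
multi-TF region sets; and a literal per-base evaluation of the three
accumulation definitions to serve as ground truth for the run-length
engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .regions import BindingRegion, RegionSet

__all__ = [
    "SyntheticSpec",
    "fig3_fixture",
    "example_fixture",
    "random_regions",
    "naive_accumulation",
    "naive_profile",
]

# The worked example: 10 binding regions of TFs X, Y, Z on one chromosome.
# The two Z regions [2800,4500] and [4250,6000] overlap exactly in
# [4250,4500] (the only same-TF overlap), so at w=0 the TF accumulation is
# 2 there while region and base accumulation are 3; with w=1000 the window
# of base 3250, [2250,4250], touches four regions of all three TFs.
_EXAMPLE_ROWS = (
    ("chrE", 100, 600, "*", "X"),
    ("chrE", 300, 900, "*", "Y"),
    ("chrE", 500, 1100, "*", "Z"),
    ("chrE", 2300, 2600, "*", "X"),
    ("chrE", 2800, 4500, "*", "Z"),
    ("chrE", 4000, 5000, "*", "Y"),
    ("chrE", 4250, 6000, "*", "Z"),
    ("chrE", 6500, 7000, "*", "X"),
    ("chrE", 6800, 7400, "*", "Y"),
    ("chrE", 7200, 7800, "*", "Z"),
)


def example_fixture() -> RegionSet:
    """The ten-region, three-TF worked-example dataset (1-based inclusive)."""
    return RegionSet(BindingRegion(*row) for row in _EXAMPLE_ROWS)


# alias kept for discoverability in tests/scripts
fig3_fixture = example_fixture


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a random binding-region dataset.

    Defaults emulate a small ChIP-seq-like input: peak lengths uniform in
    150-500 bp (typical narrow-peak widths), regions scattered over a
    100 kb span densely enough that a sizeable fraction overlap. The same
    seed always yields the identical dataset.
    """

    n_tfs: int = 4
    n_regions: int = 50
    span: int = 100_000
    length_range: tuple[int, int] = (150, 500)
    n_chroms: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs < 1 or self.n_regions < self.n_tfs:
            raise ValueError("need n_regions >= n_tfs >= 1")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("need 1 <= min length <= max length")
        if self.span < hi:
            raise ValueError("span must fit the longest region")
        if self.n_chroms < 1:
            raise ValueError("need n_chroms >= 1")


def random_regions(spec: SyntheticSpec) -> RegionSet:
    """Generate a reproducible random RegionSet from a SyntheticSpec.

    TF labels are drawn uniformly with every TF used at least once;
    starts are uniform over the span, lengths uniform in `length_range`.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    tf_names = [f"TF{i + 1}" for i in range(spec.n_tfs)]
    # guarantee every TF appears, fill the rest uniformly
    labels = list(tf_names)
    labels += [tf_names[i] for i in rng.integers(0, spec.n_tfs, spec.n_regions - spec.n_tfs)]
    rng.shuffle(labels)
    chroms = [f"chr{i + 1}" for i in rng.integers(0, spec.n_chroms, spec.n_regions)]
    lengths = rng.integers(lo, hi + 1, spec.n_regions)
    starts = rng.integers(1, spec.span - hi + 2, spec.n_regions)
    regions = [
        BindingRegion(c, int(s), int(s + L - 1), "*", t)
        for c, s, L, t in zip(chroms, starts, lengths, labels)
    ]
    return RegionSet(regions)


def naive_accumulation(regions: RegionSet, acc_type: str, w: int, b: int,
                       chrom: str | None = None) -> int:
    """Literal per-base evaluation of one accumulation value (ground truth).

    Loops over every input region (and, for the base type, over every
    base of every region) testing intersection with the neighborhood
    [max(1, b - w), b + w]. Quadratic and slow by design; used only as an
    oracle for the run-length engine.
    """
    if b < 1:
        raise ValueError("base positions are 1-based")
    rs = list(regions) if chrom is None else list(regions.by_chrom(chrom))
    win_lo, win_hi = max(1, b - w), b + w
    if acc_type == "tf":
        tfs = set()
        for r in rs:
            if r.intersects(win_lo, win_hi):
                tfs.add(r.tf)
        return len(tfs)
    if acc_type == "region":
        return sum(1 for r in rs if r.intersects(win_lo, win_hi))
    if acc_type == "base":
        total = 0
        for r in rs:
            for d in range(r.start, r.end + 1):
                if win_lo <= d <= win_hi:
                    total += 1
        return total
    raise ValueError(f"unknown acc_type {acc_type!r}")


def naive_profile(regions: RegionSet, acc_type: str, w: int,
                  start: int, end: int, chrom: str | None = None) -> np.ndarray:
    """Vectorized form of :func:`naive_accumulation` over [start, end].

    Still a direct transcription of the per-base definitions — each base
    is tested against every region — but evaluated with array arithmetic
    so whole-track oracle comparisons stay fast.
    """
    rs = list(regions) if chrom is None else list(regions.by_chrom(chrom))
    bases = np.arange(start, end + 1, dtype=np.int64)
    win_lo = np.maximum(1, bases - w)
    win_hi = bases + w
    out = np.zeros(len(bases), dtype=np.int64)
    if acc_type == "tf":
        per_tf: dict[str, np.ndarray] = {}
        for r in rs:
            hit = (r.start <= win_hi) & (r.end >= win_lo)
            if r.tf in per_tf:
                per_tf[r.tf] |= hit
            else:
                per_tf[r.tf] = hit
        for hit in per_tf.values():
            out += hit
    elif acc_type == "region":
        for r in rs:
            out += (r.start <= win_hi) & (r.end >= win_lo)
    elif acc_type == "base":
        for r in rs:
            ov = np.minimum(r.end, win_hi) - np.maximum(r.start, win_lo) + 1
            out += np.clip(ov, 0, None)
    else:
        raise ValueError(f"unknown acc_type {acc_type!r}")
    return out
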