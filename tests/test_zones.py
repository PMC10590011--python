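"""Zone finding: the two search methods, thresholding, HOT selection."""

import math

import numpy as np
import pytest

from hotzones import (
    BindingRegion,
    RegionSet,
    SyntheticSpec,
    ThresholdSpec,
    ZoneSet,
    accumulation_stats,
    binding_region_zones,
    compute_accumulation,
    find_hot_zones,
    overlap_zones,
    random_regions,
    resolve_threshold,
    select_hot,
)
from hotzones.accumulation import AccumulationTrack
from hotzones.zones import DenseZone, ThresholdResult


def regions(*rows):
    return RegionSet(BindingRegion("chr1", s, e, "*", tf) for s, e, tf in rows)


class TestBindingRegionZones:
    def test_overlapping_regions_merge(self):
        zs = binding_region_zones(regions((1, 10, "X"), (5, 20, "Y")))
        assert [(z.start, z.end, z.index) for z in zs] == [(1, 20, 2)]

    def test_adjacent_regions_stay_separate(self):
        zs = binding_region_zones(regions((1, 10, "X"), (11, 20, "X")))
        assert [(z.start, z.end, z.index) for z in zs] == [(1, 10, 1), (11, 20, 1)]

    def test_transitive_merge_on_example(self, example_regions):
        zs = binding_region_zones(example_regions)
        triples = [(z.start, z.end, z.index) for z in zs]
        # Z[2800,4500], Y[4000,5000], Z[4250,6000] chain into one zone
        assert (2800, 6000, 2) in triples
        assert triples == [(100, 1100, 3), (2300, 2600, 1), (2800, 6000, 2), (6500, 7800, 3)]

    def test_index_counts_distinct_tfs_not_regions(self):
        zs = binding_region_zones(regions((1, 10, "X"), (5, 20, "X"), (15, 30, "X")))
        assert [(z.start, z.end, z.index) for z in zs] == [(1, 30, 1)]


class TestOverlapZones:
    def test_empty_track(self):
        zs = overlap_zones([AccumulationTrack("c", "tf", 0, [], [], [])])
        assert len(zs) == 0

    def test_runs_become_zones_on_example(self, example_regions):
        tracks = compute_accumulation(example_regions, "tf", 0)
        zs = overlap_zones(tracks)
        # the same-TF overlap [4250,4500] lies inside the value-2 run [4000,5000]
        assert any(z.start <= 4250 and z.end >= 4500 and z.index == 2 for z in zs)

    def test_zones_tile_support_with_alternating_indexes(self, small_random_regions):
        tracks = compute_accumulation(small_random_regions, "region", 7)
        zs = overlap_zones(tracks)
        track = tracks["chr1"]
        assert sum(z.length for z in zs) == track.n_nonzero_bases
        by_pos = sorted(zs, key=lambda z: z.start)
        for a, b in zip(by_pos, by_pos[1:]):
            if a.end + 1 == b.start:
                assert a.index != b.index


class TestResolveThreshold:
    def test_top_k_pct_takes_ceiling(self):
        zs = ZoneSet([DenseZone("c", i * 10, i * 10 + 5, i) for i in range(1, 11)])
        thr = resolve_threshold(ThresholdSpec("top_k_pct", 10), zones=zs)
        assert thr.threshold == 10  # m = ceil(1) = 1 zone, its index is the max

    def test_top_k_pct_100_gives_minimum_index(self):
        zs = ZoneSet([DenseZone("c", i * 10, i * 10 + 5, i) for i in range(3, 9)])
        thr = resolve_threshold(ThresholdSpec("top_k_pct", 100), zones=zs)
        assert thr.threshold == 3

    def test_k_std_constant_track(self):
        t = AccumulationTrack("c", "tf", 0, [1], [50], [5])
        thr = resolve_threshold(ThresholdSpec("k_std", 2), stats=accumulation_stats([t]))
        assert thr.threshold == 5  # sd = 0, ceil(5) = 5

    def test_k_std_two_segment_hand_case(self):
        # mean 3, sample sd sqrt(20/19) ~ 1.0260; ceil(3 + 2 sd) = 6
        t = AccumulationTrack("c", "tf", 0, [1, 11], [10, 20], [2, 4])
        thr = resolve_threshold(ThresholdSpec("k_std", 2), stats=accumulation_stats([t]))
        assert thr.threshold == 6
        assert thr.derived_from["mean"] == 3.0

    def test_absolute_passthrough(self):
        assert resolve_threshold(ThresholdSpec("absolute", 4)).threshold == 4

    def test_errors(self):
        with pytest.raises(ValueError):
            ThresholdSpec("top_k_pct", 0)
        with pytest.raises(ValueError):
            ThresholdSpec("top_k_pct", 101)
        with pytest.raises(ValueError):
            ThresholdSpec("absolute", 2.5)
        with pytest.raises(ValueError, match="non-empty"):
            resolve_threshold(ThresholdSpec("top_k_pct", 10), zones=ZoneSet([]))
        from hotzones import AccumulationStats

        with pytest.raises(ValueError, match="non-zero"):
            resolve_threshold(ThresholdSpec("k_std", 1),
                              stats=AccumulationStats(0, math.nan, math.nan, 0))


class TestSelectHot:
    def test_inclusive_with_ties(self):
        zs = ZoneSet([DenseZone("c", 1, 5, 3), DenseZone("c", 10, 15, 3),
                      DenseZone("c", 20, 25, 2)])
        hot = select_hot(zs, ThresholdResult(3, "absolute", 3))
        assert [(z.start, z.index) for z in hot] == [(1, 3), (10, 3)]

    def test_threshold_one_is_identity(self, example_regions):
        zs = binding_region_zones(example_regions)
        hot = select_hot(zs, ThresholdResult(1, "absolute", 1))
        assert list(hot) == list(zs)

    def test_example_overlap_hot_zones(self, example_regions):
        tracks = compute_accumulation(example_regions, "tf", 0)
        zs = overlap_zones(tracks)
        hot = select_hot(zs, ThresholdResult(2, "absolute", 2))
        assert all(z.index >= 2 for z in hot)
        assert any(z.start <= 4250 and z.end >= 4500 for z in hot)
        # HOT zones are exactly the runs with value >= 2
        assert {(z.start, z.end) for z in hot} == {
            (z.start, z.end) for z in zs if z.index >= 2
        }


class TestFindHotZones:
    def test_overlap_index_bounded_by_tf_count(self, example_regions):
        dense, hot, thr = find_hot_zones(
            example_regions, "overlap", "tf", 0, ThresholdSpec("absolute", 3)
        )
        assert all(z.index == 3 for z in hot)
        assert 3 == len(example_regions.tf_names)

    def test_region_index_dominates_max_tf_value(self, small_random_regions):
        zs = binding_region_zones(small_random_regions)
        track = compute_accumulation(small_random_regions, "tf", 0)["chr1"]
        for z in zs:
            assert z.index >= track.to_array(z.start, z.end).max()

    @pytest.mark.parametrize("threshold", [2, 3])
    def test_overlap_hot_contained_in_binding_region_hot(
        self, small_random_regions, threshold
    ):
        spec = ThresholdSpec("absolute", threshold)
        _, hot_br, _ = find_hot_zones(small_random_regions, "binding_region",
                                      "tf", 0, spec)
        _, hot_ov, _ = find_hot_zones(small_random_regions, "overlap",
                                      "tf", 0, spec)
        spans = [(z.start, z.end) for z in hot_br]
        for z in hot_ov:
            assert any(s <= z.start and z.end <= e for s, e in spans)

    def test_overlap_hot_bases_all_reach_threshold(self, small_random_regions):
        spec = ThresholdSpec("absolute", 2)
        _, hot, thr = find_hot_zones(small_random_regions, "overlap", "tf", 7, spec)
        track = compute_accumulation(small_random_regions, "tf", 7)["chr1"]
        for z in hot:
            assert track.to_array(z.start, z.end).min() >= thr.threshold

    def test_top_k_monotone_in_k(self, small_random_regions):
        counts = []
        for k in (5, 20, 50, 100):
            _, hot, _ = find_hot_zones(small_random_regions, "overlap", "tf", 7,
                                       ThresholdSpec("top_k_pct", k))
            counts.append(len(hot))
        assert counts == sorted(counts)

    def test_k_std_threshold_monotone_in_k(self, small_random_regions):
        thresholds, counts = [], []
        for k in (0, 1, 2, 3):
            _, hot, thr = find_hot_zones(small_random_regions, "overlap", "region", 7,
                                         ThresholdSpec("k_std", k))
            thresholds.append(thr.threshold)
            counts.append(len(hot))
        assert thresholds == sorted(thresholds)
        assert counts == sorted(counts, reverse=True)

    def test_empty_chromosome_filter(self, example_regions):
        dense, hot, thr = find_hot_zones(
            example_regions, "overlap", "tf", 0,
            ThresholdSpec("top_k_pct", 10), chroms=["chrNope"],
        )
        assert len(dense) == 0 and len(hot) == 0

    def test_per_chromosome_mode(self):
        rs = random_regions(SyntheticSpec(n_tfs=3, n_regions=40, span=20_000,
                                          n_chroms=2, seed=11))
        out = find_hot_zones(rs, "overlap", "tf", 0,
                             ThresholdSpec("top_k_pct", 50), per_chromosome=True)
        assert set(out) == rs.chromosomes
        for chrom, (dense, hot, thr) in out.items():
            assert all(z.chrom == chrom for z in dense)
            assert len(hot) <= len(dense)

    def test_brute_force_agreement_small_instances(self):
        """Zone spans and counts match a per-base reimplementation."""
        from hotzones import naive_profile

        for seed in range(3):
            rs = random_regions(SyntheticSpec(n_tfs=3, n_regions=25, span=4_000,
                                              length_range=(30, 200), seed=seed))
            prof = naive_profile(rs, "tf", 0, 1, 5_000, "chr1")
            # brute-force maximal constant non-zero runs
            expected = []
            start = None
            for i, v in enumerate(prof, start=1):
                if v and (start is None or v != cur):
                    if start is not None:
                        expected.append((start, i - 1, cur))
                    start, cur = i, v
                elif not v and start is not None:
                    expected.append((start, i - 1, cur))
                    start = None
            if start is not None:
                expected.append((start, len(prof), cur))
            tracks = compute_accumulation(rs, "tf", 0)
            zs = overlap_zones(tracks)
            assert [(z.start, z.end, z.index) for z in zs] == [
                (s, e, int(v)) for s, e, v in expected
            ]


class TestLengthStats:
    def test_stats_fields(self):
        zs = ZoneSet([DenseZone("c", 1, 10, 1), DenseZone("c", 20, 49, 2),
                      DenseZone("c", 60, 99, 1), DenseZone("c", 200, 219, 3)])
        st = zs.length_stats
        assert st["min"] == 10 and st["max"] == 40
        assert st["mean"] == 25.0
        assert st["median"] == 25.0  # mean of the two central lengths 20, 30
        assert st["sd"] == pytest.approx(np.std([10, 30, 40, 20], ddof=1))

    def test_empty_and_singleton(self):
        assert ZoneSet([]).length_stats["n"] == 0
        st = ZoneSet([DenseZone("c", 1, 5, 1)]).length_stats
        assert st["mean"] == 5.0 and math.isnan(st["sd"])
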