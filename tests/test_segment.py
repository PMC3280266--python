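import numpy as np
import pytest

from cnaprog.segment import (
    Segment,
    SegmentedProfile,
    best_arc,
    cbs_segment,
    merge_small_segments,
    profiles_to_seg,
    reduce_to_regions,
    seg_to_profiles,
)
from conftest import brute_force_best_arc, toy_probe_map


def test_constant_vector_is_single_segment():
    pm = toy_probe_map(200)
    prof = cbs_segment(np.full(200, 0.3), pm, alpha=0.01, n_perm=200, seed=1)
    assert len(prof.segments) == 1
    assert prof.segments[0].n_markers == 200
    assert prof.segments[0].seg_mean == pytest.approx(0.3)


def test_two_level_step_found_at_breakpoint():
    pm = toy_probe_map(40)
    rng = np.random.default_rng(2)
    x = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(1.0, 0.1, 20)])
    prof = cbs_segment(x, pm, alpha=0.01, n_perm=1000, seed=3)
    assert len(prof.segments) == 2
    bp = prof.segments[0].end
    assert abs(bp - 20) <= 1
    assert prof.segments[0].seg_mean == pytest.approx(0.0, abs=0.1)
    assert prof.segments[1].seg_mean == pytest.approx(1.0, abs=0.1)


def test_first_split_matches_exhaustive_oracle():
    """The selected arc of the first recursion equals the brute-force argmax
    over all arcs, for 50 random vectors with n <= 50."""
    rng = np.random.default_rng(4)
    for case in range(50):
        n = int(rng.integers(5, 51))
        x = rng.normal(0, 1, n)
        if case % 3 == 0:  # plant a shift so some cases have real structure
            a, b = sorted(rng.integers(0, n, 2))
            x[a:b] += 2.0
        i, j, u = best_arc(x)
        oi, oj, ou = brute_force_best_arc(x)
        assert (i, j) == (oi, oj)
        assert u == pytest.approx(ou, rel=1e-9)


def test_partition_property_on_noisy_profiles():
    pm = toy_probe_map(150)
    rng = np.random.default_rng(5)
    for seed in range(3):
        x = rng.normal(0, 0.2, 150)
        x[40:80] += 0.8
        prof = cbs_segment(x, pm, n_perm=300, seed=seed)
        prof.check_partition(pm)
        merged = merge_small_segments(prof)
        merged.check_partition(pm)


def test_determinism_under_fixed_seed():
    pm = toy_probe_map(120)
    rng = np.random.default_rng(6)
    x = rng.normal(0, 0.3, 120)
    a = cbs_segment(x, pm, n_perm=500, seed=42)
    b = cbs_segment(x, pm, n_perm=500, seed=42)
    assert [(s.start, s.end, s.seg_mean) for s in a.segments] == [
        (s.start, s.end, s.seg_mean) for s in b.segments
    ]


class TestMergeSmallSegments:
    def make(self, spec):
        """spec: list of (n_markers, mean) on one chromosome."""
        segs, pos = [], 0
        for n, m in spec:
            segs.append(Segment("chr1", pos, pos + n, m))
            pos += n
        return SegmentedProfile("s", segs)

    def test_merges_into_closest_mean_with_weighted_average(self):
        prof = self.make([(10, 0.9), (3, 0.7), (10, 0.1)])
        out = merge_small_segments(prof, min_markers=4)
        means = [(s.seg_mean, s.n_markers) for s in out.segments]
        assert means == [
            (pytest.approx((10 * 0.9 + 3 * 0.7) / 13), 13),
            (pytest.approx(0.1), 10),
        ]

    def test_no_op_when_all_large_enough(self):
        prof = self.make([(5, 0.2), (6, -0.1), (4, 0.4)])
        out = merge_small_segments(prof, min_markers=4)
        assert [(s.start, s.end, s.seg_mean) for s in out.segments] == [
            (s.start, s.end, s.seg_mean) for s in prof.segments
        ]

    def test_edge_segment_merges_into_only_neighbor(self):
        prof = self.make([(2, 0.9), (10, 0.0)])
        out = merge_small_segments(prof, min_markers=4)
        assert len(out.segments) == 1
        assert out.segments[0].seg_mean == pytest.approx(2 * 0.9 / 12)

    def test_tie_merges_left(self):
        # binary-exact means so the neighbor distances tie exactly
        prof = self.make([(10, 0.5), (3, 0.25), (10, 0.0)])
        out = merge_small_segments(prof, min_markers=4)
        # |0.25-0.5| == |0.25-0.0|: left neighbor wins
        assert out.segments[0].n_markers == 13
        assert out.segments[1].seg_mean == pytest.approx(0.0)

    def test_terminates_and_never_leaves_small_segments(self):
        rng = np.random.default_rng(7)
        spec = [(int(rng.integers(1, 8)), float(rng.normal())) for _ in range(30)]
        out = merge_small_segments(self.make(spec), min_markers=4)
        total = sum(n for n, _ in spec)
        assert sum(s.n_markers for s in out.segments) == total
        assert all(s.n_markers >= 4 for s in out.segments) or len(out.segments) == 1

    def test_chromosome_smaller_than_threshold_collapses_to_one(self):
        prof = self.make([(1, 0.4), (2, -0.2)])
        out = merge_small_segments(prof, min_markers=4)
        assert len(out.segments) == 1


class TestReduceToRegions:
    def test_single_sample_regions_are_its_segments(self):
        pm = toy_probe_map(30)
        prof = SegmentedProfile(
            "s1", [Segment("chr1", 0, 12, 0.5), Segment("chr1", 12, 30, 0.0)]
        )
        red = reduce_to_regions([prof], pm)
        assert red.regions[["start_idx", "end_idx"]].to_numpy().tolist() == [
            [0, 12], [12, 30]
        ]
        assert np.allclose(red.values[:, 0], [0.5, 0.0])

    def test_union_of_disjoint_breakpoints(self):
        pm = toy_probe_map(30)
        p1 = SegmentedProfile(
            "s1", [Segment("chr1", 0, 10, 1.0), Segment("chr1", 10, 30, 0.0)]
        )
        p2 = SegmentedProfile(
            "s2", [Segment("chr1", 0, 20, 0.2), Segment("chr1", 20, 30, -0.4)]
        )
        red = reduce_to_regions([p1, p2], pm)
        assert red.regions[["start_idx", "end_idx"]].to_numpy().tolist() == [
            [0, 10], [10, 20], [20, 30]
        ]
        assert np.allclose(red.values[:, 0], [1.0, 0.0, 0.0])
        assert np.allclose(red.values[:, 1], [0.2, 0.2, -0.4])

    def test_reduction_is_lossless_at_probe_resolution(self):
        pm = toy_probe_map(100)
        rng = np.random.default_rng(8)
        profiles = []
        for s in range(5):
            x = rng.normal(0, 0.2, 100)
            x[20 + 5 * s : 60] += 0.9
            profiles.append(cbs_segment(x, pm, n_perm=300, seed=50 + s))
        red = reduce_to_regions(profiles, pm)
        expanded = red.expand_to_probes(100)
        for s, prof in enumerate(profiles):
            assert np.array_equal(expanded[:, s], prof.per_probe_means(100))


def test_seg_frame_round_trip_preserves_breakpoints():
    pm = toy_probe_map(50)
    prof = SegmentedProfile(
        "s1",
        [Segment("chr1", 0, 7, 0.3), Segment("chr1", 7, 33, -0.1),
         Segment("chr1", 33, 50, 0.8)],
    )
    seg = profiles_to_seg([prof], pm)
    back = seg_to_profiles(seg, pm)
    assert [(s.start, s.end) for s in back[0].segments] == [
        (s.start, s.end) for s in prof.segments
    ]


def test_parameter_validation():
    pm = toy_probe_map(10)
    with pytest.raises(ValueError):
        cbs_segment(np.zeros(10), pm, alpha=1.5)
    with pytest.raises(ValueError):
        cbs_segment(np.zeros(10), pm, n_perm=10)
    with pytest.raises(ValueError):
        cbs_segment(np.zeros(5), pm)
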