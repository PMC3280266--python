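import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from cnaprog.gistic import (
    GisticPeak,
    classify_broad_focal,
    find_peaks,
    gscore,
    permutation_null,
    qvalues,
    scan,
)
from cnaprog.segment import ReducedMatrix


def make_reduced(values, chrom="chr1", markers_each=1, region_bp=100_000):
    """Region x sample ReducedMatrix with uniform region geometry."""
    values = np.asarray(values, dtype=float)
    n_regions = values.shape[0]
    chroms = [chrom] * n_regions if isinstance(chrom, str) else chrom
    starts = np.arange(n_regions) * region_bp
    regions = pd.DataFrame(
        {
            "chrom": chroms,
            "start_idx": np.arange(n_regions) * markers_each,
            "end_idx": (np.arange(n_regions) + 1) * markers_each,
            "start": starts,
            "end": starts + region_bp,
            "n_markers": markers_each,
            "arm": "q",
        }
    )
    samples = [f"S{i}" for i in range(values.shape[1])]
    return ReducedMatrix(regions, values, samples)


def gscore_oracle(values, theta):
    """One-line independent definition: frequency x mean amplitude among
    aberrant samples, per kind."""
    amp = np.where(values >= theta, values, 0.0).sum(axis=1) / values.shape[1]
    dele = np.where(values <= -theta, -values, 0.0).sum(axis=1) / values.shape[1]
    return amp, dele


class TestGScore:
    def test_two_sample_hand_case(self):
        red = make_reduced([[0.8, 0.6]])
        t = gscore(red)
        assert t.freq_amp[0] == pytest.approx(1.0)
        assert t.g_amp[0] == pytest.approx(0.7)  # frequency 1 x mean amplitude 0.7

    def test_four_sample_mixed_hand_case(self):
        red = make_reduced([[0.8, 0.6, 0.1, -0.5]])
        t = gscore(red)
        assert t.freq_amp[0] == pytest.approx(0.5)
        assert t.g_amp[0] == pytest.approx((0.8 + 0.6) / 4)
        assert t.freq_del[0] == pytest.approx(0.25)
        assert t.g_del[0] == pytest.approx(0.5 / 4)

    def test_no_exceedance_gives_zero(self):
        red = make_reduced([[0.1, -0.2, 0.3]])
        t = gscore(red)
        assert t.g_amp[0] == 0.0 and t.freq_amp[0] == 0.0
        assert t.g_del[0] == 0.0 and t.freq_del[0] == 0.0

    def test_matches_closed_form_oracle_exactly(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vals = rng.normal(0, 0.6, size=(12, 7))
            t = gscore(make_reduced(vals))
            oa, od = gscore_oracle(vals, 0.4)
            assert np.array_equal(t.g_amp, oa)
            assert np.array_equal(t.g_del, od)

    def test_nonpositive_theta_rejected(self):
        with pytest.raises(ValueError):
            gscore(make_reduced([[0.5]]), theta_amp=0.0)


class TestPermutationNull:
    def test_pvalues_uniform_under_iid_null(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 0.5, size=(2000, 40))
        p_amp, p_del = permutation_null(make_reduced(vals), n_perm=500, seed=3)
        assert kstest(p_amp, "uniform").statistic < 0.1
        assert kstest(p_del, "uniform").statistic < 0.1

    def test_max_g_marker_has_min_p(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 0.5, size=(100, 15))
        vals[17, :] += 2.0
        track = scan(make_reduced(vals), n_perm=500, seed=5)
        assert np.argmax(track.g_amp) == 17
        assert track.p_amp[17] == track.p_amp.min()

    def test_amplifying_a_marker_never_raises_its_p(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 0.5, size=(60, 10))
        boosted = vals.copy()
        boosted[30, boosted[30] >= 0.4] *= 2
        p1, _ = permutation_null(make_reduced(vals), n_perm=500, seed=7)
        p2, _ = permutation_null(make_reduced(boosted), n_perm=500, seed=7)
        assert p2[30] <= p1[30]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(0, 0.5, size=(50, 8))
        a = permutation_null(make_reduced(vals), n_perm=500, seed=9)
        b = permutation_null(make_reduced(vals), n_perm=500, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_null(make_reduced([[0.5, 0.1]]), n_perm=100)


class TestQValues:
    def test_hand_bh_case(self):
        q = qvalues(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(qvalues(np.ones(5)), 1.0)

    def test_monotone_and_bounded_fuzz(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            p = rng.random(30)
            q = qvalues(p)
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-12).all()
            assert ((q >= p - 1e-12) & (q <= 1.0)).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            qvalues(np.array([0.5, 1.2]))


def implant(vals, lo, hi, samples, amount, rng=None):
    """Add a segment-like event: one value per carrier, constant across the
    event's markers (as segment means are after reduction)."""
    if rng is None:
        per_sample = np.full(len(samples), float(amount))
    else:
        per_sample = amount + rng.normal(0, 0.05, size=len(samples))
    vals[lo:hi, samples] = per_sample[None, :]


class TestFindPeaks:
    def background(self, rng, n_regions=120, n_samples=20):
        return rng.normal(0, 0.1, size=(n_regions, n_samples))

    def test_single_implanted_gain_yields_one_covering_peak(self):
        rng = np.random.default_rng(11)
        vals = self.background(rng)
        carriers = rng.random(20) < 0.6
        implant(vals, 50, 56, np.flatnonzero(carriers), 0.8, rng)
        track = scan(make_reduced(vals), n_perm=500, seed=12)
        peaks = [p for p in find_peaks(track) if p.kind == "amp"]
        assert len(peaks) == 1
        # peak limits cover the implanted interval within +/- 2 markers
        assert peaks[0].start <= (50 + 2) * 100_000
        assert peaks[0].end >= (56 - 2) * 100_000

    def test_two_disjoint_gains_yield_two_peaks(self):
        rng = np.random.default_rng(13)
        vals = self.background(rng)
        implant(vals, 20, 25, np.arange(0, 12), 0.8, rng)
        implant(vals, 80, 85, np.arange(8, 20), 0.8, rng)
        track = scan(make_reduced(vals), n_perm=500, seed=14)
        peaks = [p for p in find_peaks(track) if p.kind == "amp"]
        assert len(peaks) == 2

    def test_zero_threshold_gives_empty_list(self):
        rng = np.random.default_rng(15)
        vals = self.background(rng)
        implant(vals, 10, 15, np.arange(15), 0.9, rng)
        track = scan(make_reduced(vals), n_perm=500, seed=16)
        assert find_peaks(track, q_threshold=0.0) == []

    def test_peeloff_reports_secondary_peak_and_shrinks_g(self):
        """Two overlapping-run events carried by different samples: the
        second must surface via peel-off with a smaller score."""
        rng = np.random.default_rng(17)
        vals = self.background(rng, n_regions=60, n_samples=24)
        implant(vals, 20, 30, np.arange(0, 14), 0.9, rng)   # dominant
        implant(vals, 30, 36, np.arange(14, 24), 0.7, rng)  # contiguous, weaker
        track = scan(make_reduced(vals), n_perm=500, seed=18)
        peaks = [p for p in find_peaks(track) if p.kind == "amp"]
        assert len(peaks) >= 2
        peaks = sorted(peaks, key=lambda p: p.start)
        assert peaks[0].g_score > peaks[1].g_score
        assert peaks[1].start >= 30 * 100_000 - 2 * 100_000

    def test_del_peaks_mirror_amp_peaks(self):
        rng = np.random.default_rng(19)
        vals = self.background(rng)
        implant(vals, 40, 46, np.arange(12), 0.8, rng)
        track_pos = scan(make_reduced(vals), n_perm=500, seed=20)
        track_neg = scan(make_reduced(-vals), n_perm=500, seed=20)
        amp = [p for p in find_peaks(track_pos) if p.kind == "amp"]
        dele = [p for p in find_peaks(track_neg) if p.kind == "del"]
        assert [(p.start, p.end) for p in amp] == [(p.start, p.end) for p in dele]


class TestBroadFocal:
    def test_all_whole_arm_is_broad(self):
        lengths = np.full(10, 40_000_000)
        assert classify_broad_focal(lengths, arm_length_bp=40_000_000) == "broad"

    def test_short_events_are_focal(self):
        lengths = np.full(10, 500_000)
        assert classify_broad_focal(lengths, arm_length_bp=40_000_000) == "focal"

    def test_mixed_carriers_are_both(self):
        lengths = np.array([40_000_000] * 5 + [500_000] * 5)
        assert classify_broad_focal(lengths, arm_length_bp=40_000_000) == "both"

    def test_minor_broad_contingent_does_not_flip_label(self):
        lengths = np.array([40_000_000] * 1 + [500_000] * 9)
        assert classify_broad_focal(lengths, arm_length_bp=40_000_000) == "focal"
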