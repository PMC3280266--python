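import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from cnaprog.gistic import GisticPeak
from cnaprog.markers import (
    MarkerRegion,
    MarkerSet,
    classify_external,
    derive_markers,
    loocv,
    map_platform,
    predict,
    region_features,
    train_classifier,
)
from cnaprog.simulate import EventSpec, simulate_cohort
from conftest import small_cohort_config, toy_probe_map


def peak(chrom, start, end, kind="amp", q=0.01, freq=0.5):
    return GisticPeak(
        descriptor=chrom, kind=kind, scope="focal", chrom=chrom,
        start=start, end=end, q_value=q, frequency=freq, g_score=freq,
    )


class TestDeriveMarkers:
    def test_disjoint_peaks_are_all_unique(self):
        by_cluster = {
            1: [peak("chr17", 100, 200, "del")],
            2: [peak("chr19", 500, 800, "amp")],
        }
        ms = derive_markers(by_cluster)
        assert len(ms) == 2
        srcs = {(r.chrom, r.source_cluster) for r in ms.regions}
        assert srcs == {("chr17", 1), ("chr19", 2)}

    def test_identical_peak_in_both_clusters_excluded(self):
        by_cluster = {1: [peak("chr3", 0, 100)], 2: [peak("chr3", 0, 100)]}
        assert len(derive_markers(by_cluster)) == 0

    def test_identical_tables_give_empty_set(self):
        peaks = [peak("chr1", 0, 100), peak("chr2", 50, 80, "del")]
        assert len(derive_markers({1: peaks, 2: list(peaks)})) == 0

    def test_low_reciprocal_overlap_keeps_both(self):
        # 10% mutual overlap is below the 25% reciprocal threshold
        by_cluster = {
            1: [peak("chr5", 0, 1000)],
            2: [peak("chr5", 900, 1900)],
        }
        ms = derive_markers(by_cluster)
        kinds = sorted((r.start, r.end) for r in ms.regions)
        # overlapping same-kind unique regions are merged within kind
        assert kinds == [(0, 1900)]

    def test_kind_mismatch_never_blocks_uniqueness(self):
        by_cluster = {
            1: [peak("chr5", 0, 100, "amp")],
            2: [peak("chr5", 0, 100, "del")],
        }
        assert len(derive_markers(by_cluster)) == 2

    def test_symmetry_under_cluster_order(self):
        by1 = {1: [peak("chr2", 0, 100)], 2: [peak("chr7", 0, 100, "del")]}
        by2 = {2: [peak("chr7", 0, 100, "del")], 1: [peak("chr2", 0, 100)]}
        r1 = {(r.chrom, r.start, r.end, r.kind) for r in derive_markers(by1).regions}
        r2 = {(r.chrom, r.start, r.end, r.kind) for r in derive_markers(by2).regions}
        assert r1 == r2

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            derive_markers({1: [peak("chr1", 0, 10)]})


class TestPlatformMap:
    def marker_set(self):
        return MarkerSet([
            MarkerRegion("chr1", 10_000, 30_000, "amp", 1),
            MarkerRegion("chr2", 0, 5_000, "del", 2),
        ])

    def test_identity_platform_maps_to_own_probes(self):
        pm = toy_probe_map(50)
        ms = MarkerSet([MarkerRegion("chr1", 10_000, 13_000, "amp", 1)])
        platform = map_platform(ms, pm)
        ids = platform.targets[ms.regions[0].name]
        assert ids == ["p0010", "p0011", "p0012"]
        assert platform.flagged == []

    def test_sparse_platform_flags_empty_regions(self):
        # BAC-like platform: one probe every 1 Mb
        starts = np.arange(5) * 1_000_000
        pm = pd.DataFrame({
            "probe_id": [f"bac{i}" for i in range(5)],
            "chrom": "chr1", "start": starts, "end": starts + 150_000,
        })
        ms = MarkerSet([MarkerRegion("chr1", 400_000, 900_000, "amp", 1)])
        platform = map_platform(ms, pm)
        assert platform.flagged == [ms.regions[0].name]

    def test_marker_on_absent_chromosome_flagged(self):
        pm = toy_probe_map(10, chrom="chr1")
        ms = MarkerSet([MarkerRegion("chr9", 0, 5_000, "amp", 1)])
        platform = map_platform(ms, pm)
        assert platform.flagged == [ms.regions[0].name]

    def test_unresolvable_chromosome_names_error(self):
        pm = toy_probe_map(10)
        pm["chrom"] = "scaffold_77&"
        with pytest.raises(ValueError, match="mismatch|chromosome"):
            map_platform(self.marker_set(), pm)


def feature_cohort(rng, n=60, n_markers=8, delta=0.5, noise=0.2):
    """Feature-level generative model: marker means shifted by subgroup."""
    labels = np.repeat([0, 1], n // 2)
    X = rng.normal(0, noise, size=(n, n_markers))
    X[labels == 0, : n_markers // 2] += delta
    X[labels == 1, n_markers // 2 :] -= delta
    return pd.DataFrame(X, index=[f"S{i:03d}" for i in range(n)]), labels


class TestClassifier:
    def test_linearly_separable_loocv_is_perfect(self):
        rng = np.random.default_rng(1)
        X, y = feature_cohort(rng, delta=3.0, noise=0.1)
        acc, _ = loocv(X, y)
        assert acc == 1.0

    def test_permuted_labels_fall_to_chance(self):
        rng = np.random.default_rng(2)
        accs = []
        for rep in range(20):
            X, y = feature_cohort(rng, n=40, delta=0.0)
            accs.append(loocv(X, rng.permutation(y))[0])
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_single_class_rejected(self):
        rng = np.random.default_rng(3)
        X, _ = feature_cohort(rng)
        with pytest.raises(ValueError):
            train_classifier(X, np.zeros(len(X)))
        with pytest.raises(ValueError):
            loocv(X, np.zeros(len(X)))

    def test_accuracy_degrades_monotonically_with_noise(self):
        """Spearman trend of LOOCV accuracy vs noise level is negative."""
        noise_grid = [0.2, 0.5, 0.9, 1.4, 2.0]
        levels, accs = [], []
        for i, noise in enumerate(noise_grid):
            for rep in range(10):
                rng = np.random.default_rng(100 + 10 * i + rep)
                X, y = feature_cohort(rng, n=40, delta=0.5, noise=noise)
                levels.append(noise)
                accs.append(loocv(X, y)[0])
        rho, _ = spearmanr(levels, accs)
        assert rho < 0

    def test_prediction_deterministic(self):
        rng = np.random.default_rng(4)
        X, y = feature_cohort(rng)
        model = train_classifier(X, y)
        assert np.array_equal(predict(model, X), predict(model, X))


class TestRegionFeatures:
    def test_feature_is_mean_log2_over_region_probes(self):
        pm = toy_probe_map(10)
        vals = np.arange(30, dtype=float).reshape(10, 3)
        log2 = pd.DataFrame(vals, index=pm["probe_id"].to_numpy(), columns=list("abc"))
        ms = MarkerSet([MarkerRegion("chr1", 2_000, 5_000, "amp", 1)])
        feats = region_features(log2, pm, ms)
        expected = vals[2:5].mean(axis=0)
        assert np.allclose(feats.iloc[:, 0].to_numpy(), expected)

    def test_all_regions_unmappable_is_error(self):
        pm = toy_probe_map(10, chrom="chr1")
        ms = MarkerSet([MarkerRegion("chr9", 0, 1_000, "amp", 1)])
        log2 = pd.DataFrame(np.zeros((10, 2)), index=pm["probe_id"].to_numpy(),
                            columns=list("ab"))
        with pytest.raises(ValueError, match="features empty"):
            region_features(log2, pm, ms)


def marker_events(probs_a=(0.9, 0.1), probs_b=(0.1, 0.9)):
    return [
        EventSpec("chr1", 0, 100_000, "gain", 0.8, "focal", probs_a, label="mA"),
        EventSpec("chr2", 0, 80_000, "loss", 0.8, "focal", probs_b, label="mB"),
    ]


class TestClassifyExternal:
    def train_model(self, seed=31):
        cfg = small_cohort_config(seed=seed, n_samples=40, noise_sd=0.1,
                                  events=marker_events())
        coh = simulate_cohort(cfg)
        ms = MarkerSet([
            MarkerRegion("chr1", 0, 100_000, "amp", 1),
            MarkerRegion("chr2", 0, 80_000, "del", 2),
        ])
        feats = region_features(coh.log2, coh.probe_map, ms)
        model = train_classifier(feats, coh.truth_labels.to_numpy(), markers=ms)
        return coh, ms, model

    def test_external_equal_to_training_reproduces_predictions(self):
        coh, ms, model = self.train_model()
        feats = region_features(coh.log2, coh.probe_map, ms)
        base = predict(model, feats)
        labels, _ = classify_external(model, coh.log2, coh.probe_map)
        assert np.array_equal(labels.to_numpy(), base)

    def test_coarser_platform_subgroups_differ_in_survival(self):
        """External cohorts on a 10x sparser platform, same generative
        subgroups with a PFS/OS hazard contrast: the predicted subgroups
        separate survival (log-rank p < 0.05) in most replicates."""
        _, _, model = self.train_model()
        hits = 0
        for rep in range(10):
            cfg = small_cohort_config(
                seed=800 + rep, n_samples=80, noise_sd=0.1,
                events=marker_events(),
            )
            # 5x sparser platform; its probe midpoints still fall inside the
            # marker regions, mirroring a coarse BAC array over wide loci
            cfg = dataclasses.replace(cfg, probe_spacing=108_500)
            ext = simulate_cohort(cfg)
            labels, comps = classify_external(
                model, ext.log2, ext.probe_map, clinical=ext.clinical,
                endpoints=("PFS",),
            )
            hits += comps[0].logrank_p < 0.05
        assert hits >= 8

    def test_three_generative_subgroups_recovered_at_k3(self):
        events = [
            EventSpec("chr1", 0, 100_000, "gain", 0.8, "focal", (0.95, 0.02, 0.02), label="e1"),
            EventSpec("chr2", 0, 80_000, "loss", 0.8, "focal", (0.02, 0.95, 0.02), label="e2"),
            EventSpec("chr3", 0, 90_000, "gain", 0.8, "focal", (0.02, 0.02, 0.95), label="e3"),
        ]
        from cnaprog.simulate import CohortConfig

        cfg = CohortConfig(
            seed=41, n_samples=60, noise_sd=0.05, events=tuple(events),
            subgroup_proportions=(1 / 3, 1 / 3, 1 / 3),
            attenuation=1.0, genome_scale=0.002,
        )
        ext = simulate_cohort(cfg)
        ms = MarkerSet([
            MarkerRegion("chr1", 0, 100_000, "amp", 1),
            MarkerRegion("chr2", 0, 80_000, "del", 2),
            MarkerRegion("chr3", 0, 90_000, "amp", 1),
        ])
        # train a binary model on two of the groups; k=3 requests
        # supervised clustering in marker-feature space instead
        tr = simulate_cohort(small_cohort_config(
            seed=42, n_samples=30, noise_sd=0.1, events=marker_events()))
        feats_tr = region_features(tr.log2, tr.probe_map, ms)
        model = train_classifier(feats_tr, tr.truth_labels.to_numpy(), markers=ms)
        labels, _ = classify_external(model, ext.log2, ext.probe_map, k=3)
        assert labels.nunique() == 3
        assert adjusted_rand_score(ext.truth_labels, labels) > 0.8
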