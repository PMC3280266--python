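"""End-to-end pipeline orchestration with a single config and manifest.

Stage order: simulate (or load) -> CNV mask -> CBS segmentation (+ small-
segment merge) -> MAD calling -> region reduction -> cohort-level
significance scan -> Ward clustering (k-cut) + survival comparison ->
per-cluster scans -> discriminating-marker derivation -> LOOCV of the
marker classifier.  Every run writes its outputs, a config snapshot, and a
manifest of SHA-256 hashes into a fresh run directory; a rerun with the
same config reproduces the directory byte for byte (no timestamps are ever
written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cgh_io
from .calling import call_alterations, write_calls
from .gistic import find_peaks, peaks_to_frame, scan
from .markers import derive_markers, loocv, region_features
from .segment import (
    ReducedMatrix,
    profiles_to_seg,
    reduce_to_regions,
    segment_cohort,
)
from .simulate import CohortConfig, default_reference_scenario, simulate_cohort
from .subgroups import compare_survival, cut_k, tree_to_newick, ward_cluster

log = logging.getLogger("cnaprog.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str
    seed: int
    # inputs: either a simulation config or paths to an existing cohort
    simulate: CohortConfig | None = None
    probe_map_path: str | None = None
    log2_path: str | None = None
    clinical_path: str | None = None
    normals_path: str | None = None  # normal-vs-reference log2 TSV for the CNV mask
    # stage parameters
    alpha: float = 0.01
    n_perm_cbs: int = 1000
    min_markers: int = 4
    mad_scale: float = 1.11
    min_normals: int = 2
    theta_amp: float = 0.4
    theta_del: float = 0.4
    q_threshold: float = 0.25
    n_perm_gistic: int = 1000
    k: int = 2
    exclude_chrx: bool = True
    reciprocal_overlap: float = 0.25
    svm_c: float = 1.0

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        if self.simulate is None and not (self.probe_map_path and self.log2_path):
            raise ValueError("config needs either a simulation block or input paths")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # run-specific location, not part of the analysis config
        if self.simulate is not None:
            d["simulate"] = _cohort_config_dict(self.simulate)
        return d


def _cohort_config_dict(cfg: CohortConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["events"] = [dataclasses.asdict(e) for e in cfg.events]
    return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    config.validate()
    run_dir = Path(config.outdir)
    if run_dir.exists() and any(run_dir.iterdir()):
        raise ValueError(f"run directory {run_dir} exists and is not empty")
    run_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    # --- inputs
    stage = "simulate" if config.simulate is not None else "load"
    try:
        if config.simulate is not None:
            cohort = simulate_cohort(config.simulate)
            probe_map, log2, clinical = cohort.probe_map, cohort.log2, cohort.clinical
            cgh_io.write_cohort(cohort, run_dir)
        else:
            cohort = None
            probe_map = cgh_io.read_probe_map(config.probe_map_path)
            log2 = cgh_io.read_log2(config.log2_path, probe_map)
            clinical = (
                cgh_io.read_clinical(config.clinical_path)
                if config.clinical_path
                else None
            )
            cgh_io.write_probe_map(probe_map, run_dir / "probe_map.tsv")
            cgh_io.write_log2(log2, run_dir / "log2.tsv")
            if clinical is not None:
                cgh_io.write_clinical(clinical, run_dir / "clinical.tsv")
    except Exception as exc:  # noqa: BLE001 - stage context matters more
        raise StageError(stage, exc) from exc

    # --- CNV mask
    try:
        if config.normals_path:
            normals = cgh_io.read_log2(config.normals_path, probe_map)
            mask = cgh_io.derive_cnv_mask(
                normals, probe_map, min_normals=config.min_normals,
                mad_scale=config.mad_scale, alpha=config.alpha,
                n_perm=config.n_perm_cbs, seed=config.seed + 101,
            )
        else:
            mask = cgh_io.CNVMask(())
        cgh_io.mask_to_json(mask, run_dir / "cnv_mask.json")
        if len(mask):
            log2, probe_map = cgh_io.apply_mask(log2, probe_map, mask)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("mask", exc) from exc

    # --- segmentation
    try:
        profiles = segment_cohort(
            log2, probe_map, alpha=config.alpha, n_perm=config.n_perm_cbs,
            seed=config.seed + 1000, min_markers=config.min_markers,
        )
        cgh_io.write_seg(profiles_to_seg(profiles, probe_map), run_dir / "segments.seg")
    except Exception as exc:  # noqa: BLE001
        raise StageError("segment", exc) from exc

    # --- calling
    try:
        cm = call_alterations(profiles, probe_map, scale=config.mad_scale)
        write_calls(cm, run_dir / "calls.tsv", run_dir / "thresholds.json")
        for sample, (g, _) in cm.thresholds.items():
            if g == 0:
                warnings.append(f"degenerate MAD threshold (0) for sample {sample}")
    except Exception as exc:  # noqa: BLE001
        raise StageError("call", exc) from exc

    # --- reduction + cohort-level scan
    try:
        reduced = reduce_to_regions(profiles, probe_map)
        track = scan(
            reduced, theta_amp=config.theta_amp, theta_del=config.theta_del,
            n_perm=config.n_perm_gistic, seed=config.seed + 2000,
        )
        peaks = find_peaks(track, q_threshold=config.q_threshold, probe_map=probe_map)
        track.to_frame().to_csv(run_dir / "score_track.tsv", sep="\t", index=False)
        peaks_to_frame(peaks).to_csv(run_dir / "gistic_peaks.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("gistic", exc) from exc

    # --- clustering + survival
    try:
        tree = ward_cluster(reduced, exclude_chrX=config.exclude_chrx)
        labels = cut_k(tree, config.k, sample_ids=reduced.samples)
        labels.rename_axis("sample").reset_index().to_csv(
            run_dir / "clusters.tsv", sep="\t", index=False
        )
        (run_dir / "dendrogram.nwk").write_text(
            tree_to_newick(tree, reduced.samples) + "\n"
        )
        survival = {}
        if clinical is not None:
            for ep in ("PFS", "OS"):
                try:
                    survival[ep] = compare_survival(clinical, labels, endpoint=ep).summary_dict()
                except ValueError as exc:
                    warnings.append(f"survival comparison {ep}: {exc}")
        _json_dump(survival, run_dir / "survival.json")
    except Exception as exc:  # noqa: BLE001
        raise StageError("cluster", exc) from exc

    # --- per-cluster scans + markers + LOOCV
    try:
        peaks_by_cluster = {}
        for c in sorted(labels.unique()):
            idx = np.flatnonzero((labels == c).to_numpy())
            sub = ReducedMatrix(
                reduced.regions, reduced.values[:, idx],
                [reduced.samples[i] for i in idx],
            )
            tr = scan(
                sub, theta_amp=config.theta_amp, theta_del=config.theta_del,
                n_perm=config.n_perm_gistic, seed=config.seed + 3000 + int(c),
            )
            pk = find_peaks(tr, q_threshold=config.q_threshold, probe_map=probe_map)
            for p in pk:
                p.cluster = int(c)
            peaks_by_cluster[int(c)] = pk
            peaks_to_frame(pk).to_csv(
                run_dir / f"gistic_peaks_cluster{c}.tsv", sep="\t", index=False
            )
        marker_set = derive_markers(peaks_by_cluster, config.reciprocal_overlap)
        bed = marker_set.to_bed_frame()
        if len(bed):
            cgh_io.write_bed(bed, run_dir / "markers.bed")
        else:
            (run_dir / "markers.bed").write_text("")
        _json_dump(
            {
                "reciprocal_overlap": config.reciprocal_overlap,
                "markers": [dataclasses.asdict(r) for r in marker_set.regions],
            },
            run_dir / "markers.json",
        )
        loocv_out = {"n_markers": len(marker_set)}
        if len(marker_set) and labels.nunique() > 1:
            feats = region_features(log2, probe_map, marker_set)
            acc, preds = loocv(feats, labels.to_numpy(), C=config.svm_c)
            loocv_out["accuracy_vs_clusters"] = acc
            pd.DataFrame(
                {"sample": list(feats.index), "cluster": labels.to_numpy(),
                 "loocv_prediction": preds}
            ).to_csv(run_dir / "loocv_predictions.tsv", sep="\t", index=False)
            if cohort is not None:
                truth = cohort.truth_labels.loc[list(feats.index)].to_numpy()
                maps = [
                    float(np.mean((preds == a) == (truth == b)))
                    for a, b in ((1, 0), (1, 1))
                ]
                loocv_out["accuracy_vs_truth"] = max(maps)
        _json_dump(loocv_out, run_dir / "loocv.json")
    except Exception as exc:  # noqa: BLE001
        raise StageError("markers", exc) from exc

    # --- snapshot, report, manifest
    (run_dir / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    _json_dump(sorted(set(warnings)), run_dir / "warnings.json")
    (run_dir / "report.txt").write_text(report(run_dir))
    manifest = {
        "parameters": config.to_dict(),
        "files": {
            p.name: _sha256(p)
            for p in sorted(run_dir.iterdir())
            if p.name != "manifest.json"
        },
    }
    _json_dump(manifest, run_dir / "manifest.json")
    return run_dir


def report(run_dir) -> str:
    """Human-readable run summary, regenerable byte-identically."""
    run_dir = Path(run_dir)
    lines = ["copy-number pipeline run summary", "=" * 34]
    missing = [
        f for f in ("log2.tsv", "segments.seg", "gistic_peaks.tsv",
                    "clusters.tsv", "markers.json", "loocv.json")
        if not (run_dir / f).exists()
    ]
    if missing:
        lines.append("INCOMPLETE RUN; missing stages/outputs: " + ", ".join(missing))
        return "\n".join(lines) + "\n"

    cfg = yaml.safe_load((run_dir / "config.yaml").read_text())
    log2 = pd.read_csv(run_dir / "log2.tsv", sep="\t", index_col=0, nrows=1)
    n_probes = sum(1 for _ in open(run_dir / "log2.tsv")) - 1
    lines.append(f"cohort: {log2.shape[1]} samples x {n_probes} probes")
    lines.append(
        "parameters: alpha={alpha} n_perm_cbs={n_perm_cbs} min_markers={min_markers} "
        "mad_scale={mad_scale} theta=({theta_amp},{theta_del}) q<{q_threshold} "
        "k={k} svm_c={svm_c} seed={seed}".format(**cfg)
    )

    peaks = pd.read_csv(run_dir / "gistic_peaks.tsv", sep="\t")
    lines.append(f"\nsignificant peaks (cohort scan): {len(peaks)}")
    if len(peaks):
        lines.append(
            peaks[["descriptor", "kind", "scope", "peak_limits", "q_value",
                   "frequency_pct"]].to_string(index=False)
        )

    clusters = pd.read_csv(run_dir / "clusters.tsv", sep="\t")
    sizes = clusters["cluster"].value_counts().sort_index()
    lines.append("\ncluster sizes: " + ", ".join(f"{c}: n={n}" for c, n in sizes.items()))

    surv = json.loads((run_dir / "survival.json").read_text())
    for ep, s in sorted(surv.items()):
        med = ", ".join(
            f"cluster {g}: {f'{m:.1f}' if m is not None else 'not reached'}"
            for g, m in sorted(s["median_survival"].items())
        )
        lines.append(
            f"{ep}: log-rank p = {s['logrank_p']:.4g}, "
            f"HR = {s['hazard_ratio']:.3g} "
            f"({s['hr_ci'][0]:.3g}-{s['hr_ci'][1]:.3g}); median months: {med}"
        )

    markers = json.loads((run_dir / "markers.json").read_text())["markers"]
    if not markers:
        lines.append("\nno discriminating markers")
    else:
        lines.append(f"\ndiscriminating markers: {len(markers)}")
        for m in markers:
            lines.append(
                f"  {m['kind']} {m['chrom']}:{m['start']}-{m['end']} "
                f"(cluster {m['source_cluster']})"
            )
    lc = json.loads((run_dir / "loocv.json").read_text())
    if "accuracy_vs_clusters" in lc:
        lines.append(f"LOOCV accuracy vs cluster labels: {lc['accuracy_vs_clusters']:.3f}")
    if "accuracy_vs_truth" in lc:
        lines.append(f"LOOCV accuracy vs generative subgroups: {lc['accuracy_vs_truth']:.3f}")

    warn = json.loads((run_dir / "warnings.json").read_text())
    if warn:
        lines.append("\nwarnings:")
        lines.extend(f"  - {w}" for w in warn)
    return "\n".join(lines) + "\n"


def scenario_run_config(outdir: str, seed: int, n_samples: int = 72) -> RunConfig:
    """Convenience: a RunConfig for the reference scenario."""
    return RunConfig(
        outdir=outdir, seed=seed,
        simulate=default_reference_scenario(seed=seed, n_samples=n_samples),
    )


def scenario_marker_analysis(
    seed: int,
    n_samples: int = 72,
    noise_sd: float = 0.15,
    k: int = 2,
) -> dict:
    """In-memory scenario run: simulate -> segment -> cluster -> per-cluster
    scans -> markers -> LOOCV, scored against the generative truth.

    Returns the per-seed quantities the reference scenario is designed to
    probe: how many of the eight implanted discriminating regions are
    recovered by a matching-kind marker, the LOOCV accuracy of the marker
    classifier against the cluster labels it was trained on, and the same
    predictions scored against the generative subgroup labels (under the
    better of the two label mappings, since cluster numbering is
    arbitrary).
    """
    from .markers import derive_markers as _derive
    from .simulate import discriminating_events

    cfg = default_reference_scenario(seed=seed, n_samples=n_samples, noise_sd=noise_sd)
    cohort = simulate_cohort(cfg)
    profiles = segment_cohort(
        cohort.log2, cohort.probe_map, seed=cfg.seed + 1000
    )
    reduced = reduce_to_regions(profiles, cohort.probe_map)
    tree = ward_cluster(reduced, exclude_chrX=True)
    labels = cut_k(tree, k, sample_ids=reduced.samples)
    peaks_by = {}
    for c in sorted(labels.unique()):
        idx = np.flatnonzero((labels == c).to_numpy())
        sub = ReducedMatrix(
            reduced.regions, reduced.values[:, idx],
            [reduced.samples[i] for i in idx],
        )
        tr = scan(sub, seed=cfg.seed + 3000 + int(c))
        peaks_by[int(c)] = find_peaks(tr, probe_map=cohort.probe_map)
    marker_set = _derive(peaks_by)

    implants = discriminating_events(cfg)
    kind_of = {"gain": "amp", "loss": "del"}
    recovered = {
        e.label
        for e in implants
        if any(
            r.kind == kind_of[e.kind]
            and r.chrom == e.chrom
            and r.start < e.end
            and r.end > e.start
            for r in marker_set.regions
        )
    }
    out = {
        "seed": seed,
        "n_implants": len(implants),
        "n_recovered": len(recovered),
        "recovered": sorted(recovered),
        "n_markers": len(marker_set),
        "cluster_sizes": labels.value_counts().sort_index().tolist(),
    }
    feats = region_features(cohort.log2, cohort.probe_map, marker_set)
    acc, preds = loocv(feats, labels.to_numpy())
    truth = cohort.truth_labels.loc[list(feats.index)].to_numpy()
    out["loocv_vs_clusters"] = acc
    out["loocv_vs_truth"] = max(
        float(np.mean((preds == 1) == (truth == g))) for g in (0, 1)
    )
    return out
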