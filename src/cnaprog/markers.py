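"""Cluster-discriminating markers and supervised classification.

A peak from one cluster's significance scan is *unique* when no same-kind
peak from any other cluster overlaps it with at least ``reciprocal_overlap``
of both intervals (0.25 default); unique peaks from all clusters, merged
within kind, form the discriminating marker set.  Per-sample features are
region-mean log2 ratios over each marker region (continuous, preserving
amplitude); the classifier is a linear max-margin SVM (features greatly
outnumber samples, so a linear kernel is the conservative choice) evaluated
by leave-one-out cross-validation.  External cohorts on other platforms are
classified after an interval-overlap join mapping each marker region to the
external platform's probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .genome import normalize_chrom
from .gistic import GisticPeak
from .subgroups import SurvivalComparison, compare_survival, cut_k, ward_cluster

log = logging.getLogger("cnaprog.markers")


@dataclass(frozen=True)
class MarkerRegion:
    chrom: str
    start: int
    end: int
    kind: str  # "amp" | "del"
    source_cluster: object

    @property
    def name(self) -> str:
        return f"{self.kind}_{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, other: "MarkerRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.kind == other.kind
            and self.start < other.end
            and self.end > other.start
        )


@dataclass
class MarkerSet:
    regions: list[MarkerRegion]
    provenance: dict = field(default_factory=dict)  # cluster -> peak table
    reciprocal_overlap: float = 0.25

    def __len__(self) -> int:
        return len(self.regions)

    def to_bed_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"chrom": r.chrom, "start": r.start, "end": r.end, "name": r.name}
                for r in self.regions
            ]
        )


def _reciprocal(a: GisticPeak, b: GisticPeak, frac: float) -> bool:
    if a.chrom != b.chrom:
        return False
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return False
    return ov >= frac * a.length and ov >= frac * b.length


def derive_markers(
    peaks_by_cluster: dict[object, list[GisticPeak]],
    reciprocal_overlap: float = 0.25,
) -> MarkerSet:
    """Unique peaks per cluster, merged within kind across clusters."""
    if len(peaks_by_cluster) < 2:
        raise ValueError("need peak tables from at least 2 clusters")
    unique: list[MarkerRegion] = []
    for cluster, peaks in peaks_by_cluster.items():
        others = [
            p
            for c, plist in peaks_by_cluster.items()
            if c != cluster
            for p in plist
        ]
        for p in peaks:
            shared = any(
                o.kind == p.kind and _reciprocal(p, o, reciprocal_overlap)
                for o in others
            )
            if not shared:
                unique.append(
                    MarkerRegion(p.chrom, p.start, p.end, p.kind, cluster)
                )
    merged = _merge_within_kind(unique)
    return MarkerSet(
        merged,
        provenance={c: list(p) for c, p in peaks_by_cluster.items()},
        reciprocal_overlap=reciprocal_overlap,
    )


def _merge_within_kind(regions: list[MarkerRegion]) -> list[MarkerRegion]:
    out: list[MarkerRegion] = []
    for kind in ("amp", "del"):
        of_kind = sorted(
            (r for r in regions if r.kind == kind),
            key=lambda r: (r.chrom, r.start),
        )
        for r in of_kind:
            if out and out[-1].kind == kind and out[-1].overlaps(r):
                prev = out.pop()
                keep = prev if (prev.end - prev.start) >= (r.end - r.start) else r
                out.append(
                    MarkerRegion(
                        r.chrom,
                        min(prev.start, r.start),
                        max(prev.end, r.end),
                        kind,
                        keep.source_cluster,
                    )
                )
            else:
                out.append(r)
    return out


# --- platform mapping -------------------------------------------------------

@dataclass
class PlatformMap:
    """marker region -> overlapping external probe ids; empty = flagged."""

    targets: dict[str, list[str]]
    flagged: list[str]

    def usable(self, markers: MarkerSet) -> list[MarkerRegion]:
        return [r for r in markers.regions if r.name not in self.flagged]


def map_platform(markers: MarkerSet, external_probe_map: pd.DataFrame) -> PlatformMap:
    """Interval-overlap join of marker regions onto an external platform."""
    from .genome import CHROM_ORDER

    pm = external_probe_map
    try:
        pm_chroms = pm["chrom"].map(normalize_chrom)
    except ValueError as exc:
        raise ValueError(f"coordinate-space mismatch: {exc}") from exc
    unknown = set(pm_chroms.unique()) - set(CHROM_ORDER)
    if unknown:
        raise ValueError(
            f"coordinate-space mismatch: unresolvable chromosome name(s) "
            f"{sorted(unknown)[:3]} on the external platform"
        )
    targets: dict[str, list[str]] = {}
    flagged: list[str] = []
    for r in markers.regions:
        sel = (pm_chroms == r.chrom) & (pm["start"] < r.end) & (pm["end"] > r.start)
        ids = pm.loc[sel, "probe_id"].tolist()
        targets[r.name] = ids
        if not ids:
            flagged.append(r.name)
            log.warning("marker %s has no overlapping target on the external platform", r.name)
    return PlatformMap(targets, flagged)


def region_features(
    log2: pd.DataFrame,
    probe_map: pd.DataFrame,
    markers: MarkerSet,
    platform_map: PlatformMap | None = None,
) -> pd.DataFrame:
    """Samples x markers feature matrix: mean log2 over each region's probes.

    With a PlatformMap the mean is taken over the mapped external targets;
    flagged (unmappable) regions are excluded from the features.
    """
    if platform_map is None:
        platform_map = map_platform(markers, probe_map)
    cols = {}
    for r in platform_map.usable(markers):
        ids = platform_map.targets[r.name]
        cols[r.name] = log2.loc[ids].mean(axis=0)
    if not cols:
        raise ValueError("no marker region maps to the platform; features empty")
    return pd.DataFrame(cols)


# --- classifier -------------------------------------------------------------

@dataclass
class ClassifierModel:
    markers: MarkerSet
    svm: SVC
    feature_names: list[str]
    classes: np.ndarray
    C: float

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.svm.predict(features[self.feature_names].to_numpy())


def train_classifier(
    features: pd.DataFrame, labels, C: float = 1.0, markers: MarkerSet | None = None
) -> ClassifierModel:
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    svm = SVC(kernel="linear", C=C)
    svm.fit(features.to_numpy(), y)
    return ClassifierModel(
        markers=markers,
        svm=svm,
        feature_names=list(features.columns),
        classes=np.unique(y),
        C=C,
    )


def predict(model: ClassifierModel, features: pd.DataFrame) -> np.ndarray:
    return model.predict(features)


def loocv(features: pd.DataFrame, labels, C: float = 1.0) -> tuple[float, np.ndarray]:
    """Leave-one-out accuracy and the vector of held-out predictions."""
    X = features.to_numpy()
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("LOOCV requires at least 2 classes")
    if counts.min() < 3:
        raise ValueError("LOOCV requires >= 3 samples per class")
    preds = np.empty(len(y), dtype=y.dtype)
    idx = np.arange(len(y))
    for i in idx:
        tr = idx != i
        svm = SVC(kernel="linear", C=C)
        svm.fit(X[tr], y[tr])
        preds[i] = svm.predict(X[i : i + 1])[0]
    return float(np.mean(preds == y)), preds


def classify_external(
    model: ClassifierModel,
    external_log2: pd.DataFrame,
    external_probe_map: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    platform_map: PlatformMap | None = None,
    k: int | None = None,
    endpoints: tuple[str, ...] = ("OS",),
) -> tuple[pd.Series, list[SurvivalComparison]]:
    """Classify an external cohort on its own platform.

    With ``k=None`` the trained SVM assigns each sample to a training
    subgroup.  With ``k`` set, supervised clustering is used instead: the
    marker-feature space guides a Ward tree cut into k clusters (the route
    for cohorts where more than two subgroups are plausible).
    """
    if platform_map is None:
        platform_map = map_platform(model.markers, external_probe_map)
    feats = region_features(
        external_log2, external_probe_map, model.markers, platform_map
    )
    usable = [c for c in feats.columns if c in model.feature_names]
    if k is None:
        missing = [c for c in model.feature_names if c not in feats.columns]
        if missing:
            raise ValueError(
                f"external platform lacks targets for trained feature(s): {missing}"
            )
        labels = pd.Series(
            model.predict(feats), index=feats.index, name="cluster"
        )
    else:
        tree = ward_cluster(feats[usable].to_numpy())
        labels = cut_k(tree, k, sample_ids=list(feats.index))
    comparisons = []
    if clinical is not None:
        for ep in endpoints:
            comparisons.append(compare_survival(clinical, labels, endpoint=ep))
    return labels, comparisons
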