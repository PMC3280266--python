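"""Readers and writers for every on-disk artifact the pipeline touches.

Conventions (converted at the file boundary only):

* internal coordinates: 0-based half-open
* SEG on disk: 1-based inclusive (sample, chrom, start, end, n_markers, seg_mean)
* BED on disk: 0-based half-open
* chromosome dialects "19" and "chr19" both accepted, normalized to "chr19"

Also hosts the germline-CNV mask (re-derived computationally from
normal-vs-reference profiles) and gene-interval annotation of regions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import CHROM_ORDER, normalize_chrom

log = logging.getLogger("cnaprog.io")

_CHROM_RANK = {c: i for i, c in enumerate(CHROM_ORDER)}


def _chrom_sort_key(chroms: pd.Series) -> pd.Series:
    unknown = set(chroms.unique()) - set(_CHROM_RANK)
    if unknown:
        raise ValueError(f"unknown chromosome name(s): {sorted(unknown)}")
    return chroms.map(_CHROM_RANK)


# --- probe map --------------------------------------------------------------

def write_probe_map(probe_map: pd.DataFrame, path) -> None:
    probe_map.to_csv(path, sep="\t", index=False)


def read_probe_map(path) -> pd.DataFrame:
    pm = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = {"probe_id", "chrom", "start", "end"}
    missing = required - set(pm.columns)
    if missing:
        raise ValueError(f"probe map missing column(s): {sorted(missing)}")
    pm["chrom"] = pm["chrom"].map(normalize_chrom)
    if pm["probe_id"].duplicated().any():
        dups = pm.loc[pm["probe_id"].duplicated(), "probe_id"].tolist()[:5]
        raise ValueError(f"duplicate probe_id(s): {dups}")
    if (pm["end"] <= pm["start"]).any():
        raise ValueError("probe map contains intervals with end <= start")
    pm = pm.sort_values(
        ["chrom", "start"], key=lambda s: _chrom_sort_key(s) if s.name == "chrom" else s
    ).reset_index(drop=True)
    return pm


# --- log2 matrix ------------------------------------------------------------

def write_log2(log2: pd.DataFrame, path) -> None:
    log2.to_csv(path, sep="\t", index_label="probe_id")


def read_log2(path, probe_map: pd.DataFrame) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col="probe_id")
    try:
        mat = mat.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric log2 value: {exc}") from exc
    map_ids = pd.Index(probe_map["probe_id"])
    extra = mat.index.difference(map_ids)
    absent = map_ids.difference(mat.index)
    if len(extra) or len(absent):
        msg = []
        if len(extra):
            msg.append(f"probes absent from the map: {list(extra[:5])}")
        if len(absent):
            msg.append(f"map probes absent from the matrix: {list(absent[:5])}")
        raise ValueError("probe set mismatch: " + "; ".join(msg))
    mat = mat.reindex(map_ids)
    if not np.isfinite(mat.to_numpy()).all():
        raise ValueError("log2 matrix contains non-finite values")
    mat.index.name = "probe_id"
    return mat


# --- clinical table ---------------------------------------------------------

def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    cl = pd.read_csv(path, sep="\t")
    required = {"sample", "pfs_months", "pfs_event", "os_months", "os_event"}
    missing = required - set(cl.columns)
    if missing:
        raise ValueError(f"clinical table missing column(s): {sorted(missing)}")
    for col in ("pfs_months", "os_months"):
        if (cl[col] < 0).any():
            raise ValueError(f"negative survival time in column {col}")
    for col in ("pfs_event", "os_event"):
        if not cl[col].isin([0, 1]).all():
            raise ValueError(f"non-binary event indicator in column {col}")
    return cl


# --- SEG --------------------------------------------------------------------

SEG_COLUMNS = ["sample", "chrom", "start", "end", "n_markers", "seg_mean"]


def write_seg(segments: pd.DataFrame, path) -> None:
    """``segments``: internal convention (0-based half-open bp); disk is
    1-based inclusive."""
    out = segments[SEG_COLUMNS].copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    seg = pd.read_csv(path, sep="\t")
    missing = set(SEG_COLUMNS) - set(seg.columns)
    if missing:
        raise ValueError(f"SEG file missing column(s): {sorted(missing)}")
    seg["chrom"] = seg["chrom"].map(normalize_chrom)
    seg["start"] = seg["start"] - 1
    for sample, grp in seg.groupby("sample"):
        for chrom, g in grp.groupby("chrom"):
            g = g.sort_values("start")
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping segments: sample {sample}, {chrom}")
    return seg.reset_index(drop=True)


def check_seg_markers(seg: pd.DataFrame, probe_map: pd.DataFrame) -> pd.DataFrame:
    """Recompute n_markers from the probe map; on mismatch warn and let the
    probe map win."""
    seg = seg.copy()
    recomputed = np.empty(len(seg), dtype=int)
    for i, row in enumerate(seg.itertuples(index=False)):
        sel = (
            (probe_map["chrom"] == row.chrom)
            & (probe_map["start"] < row.end)
            & (probe_map["end"] > row.start)
        )
        recomputed[i] = int(sel.sum())
    bad = recomputed != seg["n_markers"].to_numpy()
    if bad.any():
        log.warning(
            "SEG n_markers inconsistent with probe map for %d segment(s); probe map wins",
            int(bad.sum()),
        )
        seg["n_markers"] = recomputed
    return seg


# --- CNV mask ---------------------------------------------------------------

@dataclass
class CNVMask:
    """Platform-level set of probes flagged as germline copy-number
    polymorphisms (per-probe, with merged bp intervals for reporting)."""

    probe_ids: tuple[str, ...]
    intervals: tuple[tuple[str, int, int], ...] = ()

    def __len__(self) -> int:
        return len(self.probe_ids)


def mask_to_json(mask: CNVMask, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"probe_ids": list(mask.probe_ids),
             "intervals": [list(iv) for iv in mask.intervals]},
            fh, indent=1)


def mask_from_json(path) -> CNVMask:
    with open(path) as fh:
        d = json.load(fh)
    return CNVMask(tuple(d["probe_ids"]), tuple(tuple(iv) for iv in d["intervals"]))


def _mask_intervals(probe_map: pd.DataFrame, flagged: np.ndarray) -> tuple:
    ivs = []
    sub = probe_map.loc[flagged]
    for chrom, g in sub.groupby("chrom", sort=False):
        starts, ends = g["start"].to_numpy(), g["end"].to_numpy()
        if len(starts) == 0:
            continue
        s, e = starts[0], ends[0]
        for st, en in zip(starts[1:], ends[1:]):
            if st <= e:
                e = max(e, en)
            else:
                ivs.append((chrom, int(s), int(e)))
                s, e = st, en
        ivs.append((chrom, int(s), int(e)))
    return tuple(ivs)


def derive_cnv_mask(
    normal_log2: pd.DataFrame,
    probe_map: pd.DataFrame,
    min_normals: int = 2,
    mad_scale: float = 1.11,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    min_markers: int = 1,
) -> CNVMask:
    """Flag probes recurrently called gain/loss across normal-vs-reference
    hybridizations.

    Each normal profile is segmented and MAD-called like a tumor, with two
    mask-specific adjustments: sub-threshold segments are kept
    (``min_markers=1`` default) because germline CNVs are often narrower
    than four probes, and the MAD is taken over probe-level ratios rather
    than segment means (a normal genome yields a handful of flat segments,
    too few for a stable segment-level MAD).  A probe called non-neutral in
    at least ``min_normals`` normals enters the mask.
    """
    from .calling import call_segments, mad_threshold
    from .segment import cbs_segment, merge_small_segments

    if normal_log2.shape[1] < 1:
        raise ValueError("at least one normal profile required")
    hits = np.zeros(len(probe_map), dtype=int)
    for i, col in enumerate(normal_log2.columns):
        values = normal_log2[col].to_numpy()
        prof = cbs_segment(
            values, probe_map, sample_id=str(col),
            alpha=alpha, n_perm=n_perm, seed=seed + i,
        )
        if min_markers > 1:
            prof = merge_small_segments(prof, min_markers)
        gain_thr, loss_thr = mad_threshold(
            prof, scale=mad_scale, probe_values=values
        )
        called = np.zeros(len(probe_map), dtype=bool)
        for seg, c in zip(prof.segments, call_segments(prof, gain_thr, loss_thr)):
            if c:
                called[seg.start : seg.end] = True
        # probe-level rescue: a single-probe germline CNV is invisible to the
        # permutation segmenter (an outlier's max-arc statistic is invariant
        # under within-stretch permutation), so strong probe-level outliers
        # (3 robust SD, and at least the segment-call threshold) are flagged
        # as well
        med = np.median(values)
        sigma = 1.4826 * np.median(np.abs(values - med))
        out_thr = max(gain_thr, 3.0 * sigma)
        called |= np.abs(values - med) > out_thr
        hits += called
    flagged = hits >= min_normals
    probe_ids = tuple(probe_map.loc[flagged, "probe_id"])
    return CNVMask(probe_ids, _mask_intervals(probe_map, flagged))


def apply_mask(
    log2: pd.DataFrame, probe_map: pd.DataFrame, mask: CNVMask
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop masked probe rows from matrix and map, preserving order."""
    masked = set(mask.probe_ids)
    keep = ~probe_map["probe_id"].isin(masked).to_numpy()
    pm = probe_map.loc[keep].reset_index(drop=True)
    mat = log2.loc[pm["probe_id"].to_numpy()]
    return mat, pm


# --- BED / gene annotation --------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader (chrom, start, end[, name]); 0-based half-open."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno}: expected >= 3 columns")
            try:
                chrom = normalize_chrom(parts[0])
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: {exc}") from exc
            if end <= start:
                raise ValueError(f"malformed BED line {lineno}: end <= start")
            name = parts[3] if len(parts) > 3 else f"feature_{lineno}"
            rows.append((chrom, start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def annotate_regions(
    regions: list[tuple[str, int, int]], genes: pd.DataFrame
) -> list[tuple[int, list[str]]]:
    """Per region: count and sorted names of genes overlapping by >= 1 bp.

    Both interval sets are 0-based half-open, so a gene abutting a region
    end is not counted.
    """
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.name)
    out = []
    for chrom, start, end in regions:
        chrom = normalize_chrom(chrom)
        hits = trees[chrom].overlap(start, end) if chrom in trees else set()
        names = sorted({h.data for h in hits})
        out.append((len(names), names))
    return out


# --- truth / misc JSON ------------------------------------------------------

def write_truth(cohort, path) -> None:
    d = {
        "labels": cohort.truth_labels.to_dict(),
        "events": {
            lab: cohort.truth_events.loc[lab].astype(int).tolist()
            for lab in cohort.truth_events.index
        },
        "samples": cohort.sample_ids,
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_cohort(cohort, outdir) -> None:
    """TSV/JSON export of a simulated cohort (round-trips through the
    readers above)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_probe_map(cohort.probe_map, outdir / "probe_map.tsv")
    write_log2(cohort.log2, outdir / "log2.tsv")
    write_clinical(cohort.clinical, outdir / "clinical.tsv")
    write_truth(cohort, outdir / "truth.json")
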