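"""GISTIC-style recurrent-alteration scan on the reduced region matrix.

Per marker (region) and kind, the G-score is

    G = frequency x mean exceedance amplitude among aberrant samples
      = (1/N) * sum over samples exceeding the threshold of |value|

with amplification aberrant at value >= theta_amp and deletion at
value <= -theta_del (theta 0.4 by default for both kinds).  Significance
comes from a within-sample marker permutation null: each sample's region
values are permuted across positions (preserving that sample's aberration
burden while destroying genomic location), permuted G-scores are pooled
across markers and permutations into one empirical null per kind, and
p(m) = (1 + #null >= G(m)) / (1 + pool size).  Benjamini-Hochberg converts
p to q; maximal runs of contiguous markers with q below the significance
threshold (0.25 default) form significant regions, whose maximal-G sub-run
is the reported peak.  Peel-off removes the peak's contributing events and
rescans the region for secondary peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .segment import ReducedMatrix

DEFAULT_THETA = 0.4
DEFAULT_Q_THRESHOLD = 0.25


def qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _gscore_arrays(values: np.ndarray, theta_amp: float, theta_del: float):
    n = values.shape[1]
    amp_mask = values >= theta_amp
    del_mask = values <= -theta_del
    g_amp = np.where(amp_mask, values, 0.0).sum(axis=1) / n
    g_del = np.where(del_mask, -values, 0.0).sum(axis=1) / n
    return g_amp, g_del, amp_mask.sum(axis=1) / n, del_mask.sum(axis=1) / n


@dataclass
class GScoreTrack:
    reduced: ReducedMatrix
    theta_amp: float
    theta_del: float
    g_amp: np.ndarray
    g_del: np.ndarray
    freq_amp: np.ndarray
    freq_del: np.ndarray
    p_amp: np.ndarray | None = None
    p_del: np.ndarray | None = None
    q_amp: np.ndarray | None = None
    q_del: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = self.reduced.regions[["chrom", "start", "end", "n_markers"]].copy()
        for name in ("g_amp", "g_del", "freq_amp", "freq_del",
                     "p_amp", "p_del", "q_amp", "q_del"):
            v = getattr(self, name)
            if v is not None:
                df[name] = v
        return df


def gscore(
    reduced: ReducedMatrix,
    theta_amp: float = DEFAULT_THETA,
    theta_del: float = DEFAULT_THETA,
) -> GScoreTrack:
    if theta_amp <= 0 or theta_del <= 0:
        raise ValueError("thresholds must be > 0")
    g_amp, g_del, f_amp, f_del = _gscore_arrays(reduced.values, theta_amp, theta_del)
    return GScoreTrack(reduced, theta_amp, theta_del, g_amp, g_del, f_amp, f_del)


def permutation_null(
    reduced: ReducedMatrix,
    theta_amp: float = DEFAULT_THETA,
    theta_del: float = DEFAULT_THETA,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-sample permutation p-values, (p_amp, p_del)."""
    p_amp, p_del, _, _ = _permutation_null_full(
        reduced, theta_amp, theta_del, n_perm, seed
    )
    return p_amp, p_del


def _permutation_null_full(
    reduced: ReducedMatrix,
    theta_amp: float = DEFAULT_THETA,
    theta_del: float = DEFAULT_THETA,
    n_perm: int = 1000,
    seed: int = 0,
    g_obs: tuple[np.ndarray, np.ndarray] | None = None,
):
    """p-values plus the sorted pooled null arrays (for peel-off rescans)."""
    if n_perm < 500:
        raise ValueError("n_perm must be >= 500")
    values = reduced.values
    if g_obs is None:
        ga, gd, _, _ = _gscore_arrays(values, theta_amp, theta_del)
    else:
        ga, gd = g_obs
    rng = np.random.default_rng(seed)
    n_regions = values.shape[0]
    null_amp = np.empty(n_perm * n_regions)
    null_del = np.empty(n_perm * n_regions)
    for b in range(n_perm):
        perm = rng.permuted(values, axis=0)  # each sample's column shuffled
        a, d, _, _ = _gscore_arrays(perm, theta_amp, theta_del)
        null_amp[b * n_regions : (b + 1) * n_regions] = a
        null_del[b * n_regions : (b + 1) * n_regions] = d
    null_amp.sort()
    null_del.sort()

    def pvals(obs, null):
        ge = null.size - np.searchsorted(null, obs, side="left")
        return (1.0 + ge) / (1.0 + null.size)

    return pvals(ga, null_amp), pvals(gd, null_del), null_amp, null_del


def scan(
    reduced: ReducedMatrix,
    theta_amp: float = DEFAULT_THETA,
    theta_del: float = DEFAULT_THETA,
    n_perm: int = 1000,
    seed: int = 0,
) -> GScoreTrack:
    """G-scores + permutation p + BH q in one call."""
    track = gscore(reduced, theta_amp, theta_del)
    p_amp, p_del, null_amp, null_del = _permutation_null_full(
        reduced, theta_amp, theta_del, n_perm, seed, g_obs=(track.g_amp, track.g_del)
    )
    track.p_amp, track.p_del = p_amp, p_del
    track.q_amp, track.q_del = qvalues(p_amp), qvalues(p_del)
    track._null = {"amp": null_amp, "del": null_del}
    return track


@dataclass
class GisticPeak:
    """One significant amplification/deletion peak (a report-table row)."""

    descriptor: str
    kind: str  # "amp" | "del"
    scope: str  # "broad" | "focal" | "both"
    chrom: str
    start: int  # bp, 0-based half-open
    end: int
    q_value: float
    frequency: float  # fraction in [0, 1]
    g_score: float
    n_genes: int | None = None
    cluster: object = None
    region_span: tuple[int, int] | None = None  # significant-region bp limits

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and self.end > start


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of True."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def _peak_subrun(g: np.ndarray, lo: int, hi: int) -> tuple[int, int]:
    """Maximal contiguous sub-run of [lo, hi) attaining the run's max G,
    containing the first argmax."""
    seg = g[lo:hi]
    top = seg.max()
    at_max = np.isclose(seg, top, rtol=0.0, atol=1e-12)
    first = int(np.argmax(at_max))
    a = first
    while a > 0 and at_max[a - 1]:
        a -= 1
    b = first
    while b + 1 < len(seg) and at_max[b + 1]:
        b += 1
    return lo + a, lo + b + 1


def classify_broad_focal(
    carrier_lengths_bp: np.ndarray,
    arm_length_bp: int,
    arm_fraction: float = 0.5,
    both_fraction: float = 0.25,
) -> str:
    """Label a peak by the lengths of its contributing sample events.

    Median carrier-event length >= arm_fraction * arm length -> broad,
    otherwise focal; if both modes hold >= both_fraction of carriers the
    label is "both".
    """
    lens = np.asarray(carrier_lengths_bp, dtype=float)
    if lens.size == 0:
        return "focal"
    cut = arm_fraction * arm_length_bp
    broad_frac = float(np.mean(lens >= cut))
    if both_fraction <= broad_frac <= 1 - both_fraction:
        return "both"
    return "broad" if np.median(lens) >= cut else "focal"


def _covering_segment(
    aber_col: np.ndarray, values_col: np.ndarray, anchor: int, lo_c: int, hi_c: int
) -> tuple[int, int]:
    """Bounds (inclusive) of the sample's covering segment at ``anchor``:
    the maximal contiguous aberrant run holding the anchor's exact segment
    value (region values inside one CBS segment are bit-identical)."""
    v = values_col[anchor]
    a = anchor
    while a > lo_c and aber_col[a - 1] and abs(values_col[a - 1] - v) <= 1e-12:
        a -= 1
    b = anchor
    while b + 1 < hi_c and aber_col[b + 1] and abs(values_col[b + 1] - v) <= 1e-12:
        b += 1
    return a, b


def _carrier_event_lengths(
    values: np.ndarray, regions: pd.DataFrame, chrom_mask: np.ndarray,
    peak_lo: int, peak_hi: int, kind: str, theta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """For each sample aberrant over the peak: bp length of its contiguous
    aberrant run through the peak.  Returns (sample indices, lengths)."""
    aber = values >= theta if kind == "amp" else values <= -theta
    peak_any = aber[peak_lo:peak_hi, :].any(axis=0)
    carrier_idx = np.flatnonzero(peak_any)
    chrom_rows = np.flatnonzero(chrom_mask)
    lo_c, hi_c = chrom_rows[0], chrom_rows[-1] + 1
    starts = regions["start"].to_numpy()
    ends = regions["end"].to_numpy()
    lengths = np.empty(len(carrier_idx))
    for out_i, s in enumerate(carrier_idx):
        anchor = peak_lo + int(np.argmax(aber[peak_lo:peak_hi, s]))
        a = anchor
        while a > lo_c and aber[a - 1, s]:
            a -= 1
        b = anchor
        while b + 1 < hi_c and aber[b + 1, s]:
            b += 1
        lengths[out_i] = ends[b] - starts[a]
    return carrier_idx, lengths


def find_peaks(
    track: GScoreTrack,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    probe_map: pd.DataFrame | None = None,
    arm_lengths: dict[tuple[str, str], int] | None = None,
    arm_fraction: float = 0.5,
    max_peeloff: int = 10,
) -> list[GisticPeak]:
    """Extract significant peaks per kind, with peel-off for secondaries.

    Arm lengths for broad/focal calls come from ``arm_lengths`` ((chrom,
    arm) -> bp) or the probe map; as a last resort they are approximated
    from the region table (coarse when a region straddles the centromere).
    """
    if track.q_amp is None or track.q_del is None:
        raise ValueError("track has no q-values; run scan() first")
    regions = track.reduced.regions
    samples = track.reduced.samples
    if arm_lengths is None and probe_map is not None:
        from .genome import arm_table

        at = arm_table(probe_map)
        arm_lengths = {
            (r.chrom, r.arm): int(r.length) for r in at.itertuples(index=False)
        }
    if arm_lengths is None:
        ext = regions.groupby(["chrom", "arm"]).agg(lo=("start", "min"), hi=("end", "max"))
        arm_lengths = {idx: int(r.hi - r.lo) for idx, r in ext.iterrows()}
    null = getattr(track, "_null", None)
    peaks: list[GisticPeak] = []
    for kind, q, theta in (
        ("amp", track.q_amp, track.theta_amp),
        ("del", track.q_del, track.theta_del),
    ):
        sig = q < q_threshold
        values = track.reduced.values.copy()
        chrom_arr = regions["chrom"].to_numpy()
        for chrom in pd.unique(chrom_arr):
            cmask = chrom_arr == chrom
            for lo, hi in _runs(sig & cmask):
                peaks.extend(
                    _peeled_peaks(
                        values, regions, cmask, lo, hi, kind, theta,
                        q, q_threshold, null, arm_lengths, arm_fraction,
                        max_peeloff, len(samples),
                    )
                )
    peaks.sort(key=lambda p: (p.kind, _chrom_rank(p.chrom), p.start))
    return peaks


def _chrom_rank(chrom: str) -> int:
    from .genome import CHROM_ORDER

    return CHROM_ORDER.index(chrom) if chrom in CHROM_ORDER else 99


def _region_q(g: np.ndarray, null: np.ndarray) -> np.ndarray:
    ge = null.size - np.searchsorted(null, g, side="left")
    p = (1.0 + ge) / (1.0 + null.size)
    return qvalues(p)


def _peeled_peaks(
    values, regions, cmask, lo, hi, kind, theta, q_track, q_threshold,
    null, arm_lengths, arm_fraction, max_peeloff, n_samples,
) -> list[GisticPeak]:
    """Primary peak of a significant run plus peel-off secondaries."""
    starts = regions["start"].to_numpy()
    ends = regions["end"].to_numpy()
    arms = regions["arm"].to_numpy()
    chroms = regions["chrom"].to_numpy()
    region_span = (int(starts[lo]), int(ends[hi - 1]))
    out: list[GisticPeak] = []
    n = values.shape[1]
    q_local = q_track[lo:hi].copy()
    for _ in range(max_peeloff):
        signed = values if kind == "amp" else -values
        g_all = np.where(
            signed >= theta, signed, 0.0
        ).sum(axis=1) / n
        if not (q_local < q_threshold).any():
            break
        # restrict the peak search to currently significant markers
        g_run = np.where(q_local < q_threshold, g_all[lo:hi], -np.inf)
        if np.all(~np.isfinite(g_run)) or g_run.max() <= 0:
            break
        p_lo, p_hi = _peak_subrun(np.where(np.isfinite(g_run), g_run, -1.0), 0, hi - lo)
        p_lo += lo
        p_hi += lo
        carrier_idx, lengths = _carrier_event_lengths(
            values, regions, cmask, p_lo, p_hi, kind, theta
        )
        arm = arms[p_lo]
        chrom = chroms[p_lo]
        scope = classify_broad_focal(
            lengths, arm_lengths.get((chrom, arm), int(ends[cmask].max() - starts[cmask].min())),
            arm_fraction,
        )
        freq = len(carrier_idx) / n
        out.append(
            GisticPeak(
                descriptor=f"{chrom.removeprefix('chr')}{arm}",
                kind=kind,
                scope=scope,
                chrom=chrom,
                start=int(starts[p_lo]),
                end=int(ends[p_hi - 1]),
                q_value=float(np.min(q_track[p_lo:p_hi])),
                frequency=freq,
                g_score=float(g_all[p_lo:p_hi].max()),
                region_span=region_span,
            )
        )
        if null is None or len(carrier_idx) == 0:
            break
        # peel off: zero each contributing sample's covering segment (the
        # equal-value aberrant run, so an adjacent event of the same sample
        # at a different amplitude survives for the rescan)
        aber = values >= theta if kind == "amp" else values <= -theta
        chrom_rows = np.flatnonzero(cmask)
        lo_c, hi_c = chrom_rows[0], chrom_rows[-1] + 1
        for s in carrier_idx:
            anchor = p_lo + int(np.argmax(aber[p_lo:p_hi, s]))
            a, b = _covering_segment(aber[:, s], values[:, s], anchor, lo_c, hi_c)
            values[a : b + 1, s] = 0.0
        signed = values if kind == "amp" else -values
        g_new = np.where(signed >= theta, signed, 0.0).sum(axis=1) / n
        q_local = _region_q(g_new[lo:hi], null[kind])
    return out


def peaks_to_frame(peaks: list[GisticPeak]) -> pd.DataFrame:
    """Report-style table: peak limits printed 1-based inclusive."""
    rows = []
    for p in peaks:
        rows.append(
            {
                "descriptor": p.descriptor,
                "kind": "Amp" if p.kind == "amp" else "Del",
                "scope": p.scope,
                "peak_limits": f"{p.chrom}:{p.start + 1}-{p.end}",
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "q_value": p.q_value,
                "frequency_pct": round(100 * p.frequency, 1),
                "n_genes": p.n_genes if p.n_genes is not None else "",
                "cluster": p.cluster if p.cluster is not None else "",
            }
        )
    return pd.DataFrame(rows)
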