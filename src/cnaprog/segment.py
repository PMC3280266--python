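"""Circular binary segmentation and cohort-level region reduction.

Each sample's log2 profile is partitioned per chromosome into constant-mean
segments by recursive circular binary splitting: for the current stretch of
n probes, the arc [i, j) maximizing

    U(i, j) = |mean(arc) - mean(complement)| / sqrt(1/k + 1/(n-k)),  k = j - i

is found (the two-sample mean-difference statistic with the constant
within-stretch variance factor dropped, which leaves both the argmax and the
permutation rank unchanged), and the split is accepted when its within-stretch
permutation p-value falls below ``alpha``.  Ties in the argmax break to the
smallest i, then smallest j.

The permutation test is sequentially curtailed: it stops as soon as the
accept/reject decision at ``alpha`` is determined (reject once exceedances
reach ceil(alpha*(n_perm+1)); accept when no exceedance has occurred after
200 permutations, where the curtailed p-value estimate is already below
alpha/2).  Decisions are deterministic given the seed.

Downstream, segments with fewer than ``min_markers`` probes are merged into
the adjacent segment closest in mean, and the cohort is reduced to the
union of all samples' breakpoints without losing any sample's segment means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .genome import normalize_chrom


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # global probe index, half-open
    end: int
    seg_mean: float

    @property
    def n_markers(self) -> int:
        return self.end - self.start


@dataclass
class SegmentedProfile:
    sample_id: str
    segments: list[Segment]
    params: dict = field(default_factory=dict)

    def per_probe_means(self, n_probes: int) -> np.ndarray:
        out = np.empty(n_probes)
        out.fill(np.nan)
        for s in self.segments:
            out[s.start : s.end] = s.seg_mean
        return out

    def check_partition(self, probe_map: pd.DataFrame) -> None:
        """Segments of each chromosome must tile its probes exactly."""
        by_chrom: dict[str, list[Segment]] = {}
        for s in self.segments:
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, segs in by_chrom.items():
            idx = np.flatnonzero((probe_map["chrom"] == chrom).to_numpy())
            segs = sorted(segs, key=lambda s: s.start)
            if segs[0].start != idx[0] or segs[-1].end != idx[-1] + 1:
                raise AssertionError(f"{chrom}: segments do not span the chromosome")
            for a, b in zip(segs, segs[1:]):
                if a.end != b.start:
                    raise AssertionError(f"{chrom}: gap/overlap at probe {a.end}")


# --- numba kernels ----------------------------------------------------------

@njit(cache=False, fastmath=True)
def _scan_max(S: np.ndarray, n: int) -> float:
    """Max of U over all distinct circular partitions; S is the cumulative
    sum with S[0] = 0.  Suffix arcs (j = n) are skipped: the complement of
    [i, n) is the prefix arc [0, i), already enumerated, so every partition
    is evaluated exactly once."""
    T = S[n]
    best = 0.0
    for k in range(1, n):
        c1 = 1.0 / k + 1.0 / (n - k)
        b = T / (n - k)
        inv = 1.0 / math.sqrt(c1)
        dmax = -1e300
        dmin = 1e300
        for i in range(0, n - k):
            d = S[i + k] - S[i]
            if d > dmax:
                dmax = d
            if d < dmin:
                dmin = d
        u = abs(c1 * dmax - b)
        u2 = abs(c1 * dmin - b)
        if u2 > u:
            u = u2
        u *= inv
        if u > best:
            best = u
    return best


@njit(cache=False)
def _scan_argmax(S: np.ndarray, n: int):
    """Argmax arc (i, j) of U with ties broken to smallest i then j.
    Suffix arcs (j = n) are skipped as duplicates of prefix arcs."""
    T = S[n]
    best = -1.0
    bi = 0
    bj = 1
    for k in range(1, n):
        c1 = 1.0 / k + 1.0 / (n - k)
        b = T / (n - k)
        inv = 1.0 / math.sqrt(c1)
        for i in range(0, n - k):
            d = S[i + k] - S[i]
            u = abs(c1 * d - b) * inv
            j = i + k
            if u > best:
                best = u
                bi = i
                bj = j
            elif u == best and (i < bi or (i == bi and j < bj)):
                bi = i
                bj = j
    return bi, bj, best


@njit(cache=False)
def _perm_decide(x: np.ndarray, obs: float, n_perm: int, reject_at: int,
                 accept_at: int, seed: int):
    """Sequentially curtailed permutation count of null max-U >= obs.

    Returns (exceedances, permutations run).
    """
    np.random.seed(seed)
    n = x.size
    y = x.copy()
    S = np.empty(n + 1)
    exceed = 0
    for m in range(1, n_perm + 1):
        np.random.shuffle(y)
        S[0] = 0.0
        acc = 0.0
        for t in range(n):
            acc += y[t]
            S[t + 1] = acc
        if _scan_max(S, n) >= obs:
            exceed += 1
            if exceed >= reject_at:
                return exceed, m
        if m == accept_at and exceed == 0:
            return 0, m
    return exceed, n_perm


def best_arc(x: np.ndarray) -> tuple[int, int, float]:
    """Best circular split of ``x``: arc bounds (i, j) and its statistic."""
    x = np.asarray(x, dtype=np.float64)
    S = np.concatenate(([0.0], np.cumsum(x)))
    return _scan_argmax(S, len(x))


def _test_split(x: np.ndarray, alpha: float, n_perm: int, seed: int):
    """Return (i, j) of an accepted split, or None."""
    n = len(x)
    if n < 2:
        return None
    i, j, obs = _scan_argmax(np.concatenate(([0.0], np.cumsum(x))), n)
    reject_at = int(math.ceil(alpha * (n_perm + 1)))
    accept_at = min(150, n_perm)
    if 1.0 / (accept_at + 1) >= alpha:
        accept_at = n_perm  # alpha too small for curtailed acceptance
    exceed, m = _perm_decide(x, obs, n_perm, reject_at, accept_at, seed)
    p = (exceed + 1) / (m + 1)
    return (i, j) if p < alpha else None


def cbs_segment(
    values: np.ndarray,
    probe_map: pd.DataFrame,
    sample_id: str = "",
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> SegmentedProfile:
    """Segment one sample's probe-ordered log2 vector per chromosome."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    values = np.asarray(values, dtype=np.float64)
    if len(values) != len(probe_map):
        raise ValueError("values length does not match probe map")

    segments: list[Segment] = []
    counter = 0
    chroms = probe_map["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        lo_g, hi_g = int(idx[0]), int(idx[-1]) + 1
        x = values[lo_g:hi_g]
        breakpoints = {0, len(x)}
        stack = [(0, len(x))]
        while stack:
            lo, hi = stack.pop()
            counter += 1
            sub_seed = (seed * 1_000_003 + counter * 7919) % (2**31 - 1)
            res = _test_split(x[lo:hi], alpha, n_perm, sub_seed)
            if res is None:
                continue
            i, j = res
            cuts = sorted({lo, lo + i, lo + j, hi})
            breakpoints.update(cuts)
            for a, b in zip(cuts, cuts[1:]):
                if b - a >= 2:
                    stack.append((a, b))
        bps = sorted(breakpoints)
        for a, b in zip(bps, bps[1:]):
            segments.append(
                Segment(chrom, lo_g + a, lo_g + b, float(np.mean(x[a:b])))
            )
    return SegmentedProfile(
        sample_id=sample_id,
        segments=segments,
        params={"alpha": alpha, "n_perm": n_perm, "seed": seed},
    )


def segment_cohort(
    log2: pd.DataFrame,
    probe_map: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    min_markers: int = 4,
) -> list[SegmentedProfile]:
    """CBS + small-segment merge for every sample of a cohort."""
    profiles = []
    for i, col in enumerate(log2.columns):
        prof = cbs_segment(
            log2[col].to_numpy(), probe_map, sample_id=str(col),
            alpha=alpha, n_perm=n_perm, seed=seed + 17 * i,
        )
        if min_markers > 1:
            prof = merge_small_segments(prof, min_markers)
        profiles.append(prof)
    return profiles


def merge_small_segments(profile: SegmentedProfile, min_markers: int = 4) -> SegmentedProfile:
    """Merge sub-threshold segments into the adjacent segment closest in mean.

    Iteratively the smallest sub-threshold segment (leftmost on ties) is
    merged into whichever neighbor has the closest seg_mean (left on ties);
    the merged mean is the probe-weighted mean.  Stops when all segments
    have >= min_markers probes or a chromosome is down to one segment.
    """
    out: list[Segment] = []
    by_chrom: dict[str, list[Segment]] = {}
    for s in profile.segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        while len(segs) > 1:
            sizes = [s.n_markers for s in segs]
            small = [i for i, n in enumerate(sizes) if n < min_markers]
            if not small:
                break
            i = min(small, key=lambda i: (sizes[i], i))
            cand = []
            if i > 0:
                cand.append((abs(segs[i].seg_mean - segs[i - 1].seg_mean), 0, i - 1))
            if i < len(segs) - 1:
                cand.append((abs(segs[i].seg_mean - segs[i + 1].seg_mean), 1, i + 1))
            _, _, j = min(cand)  # tie -> left neighbor (second key 0 < 1)
            a, b = (segs[j], segs[i]) if j < i else (segs[i], segs[j])
            n = a.n_markers + b.n_markers
            mean = (a.seg_mean * a.n_markers + b.seg_mean * b.n_markers) / n
            merged = Segment(chrom, a.start, b.end, mean)
            lo = min(i, j)
            segs[lo : lo + 2] = [merged]
        out.extend(segs)
    return SegmentedProfile(profile.sample_id, out, dict(profile.params))


# --- region reduction -------------------------------------------------------

@dataclass
class ReducedMatrix:
    """Region x sample matrix of segment means over the union of all
    samples' breakpoints; lossless with respect to per-probe segment means."""

    regions: pd.DataFrame  # chrom, start_idx, end_idx, start, end, n_markers, arm
    values: np.ndarray  # regions x samples
    samples: list[str]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def expand_to_probes(self, n_probes: int) -> np.ndarray:
        out = np.empty((n_probes, len(self.samples)))
        out.fill(np.nan)
        for r, row in enumerate(self.regions.itertuples(index=False)):
            out[row.start_idx : row.end_idx, :] = self.values[r, :]
        return out

    def sample_features(
        self, exclude_chrX: bool = False, probe_weighted: bool = True
    ) -> np.ndarray:
        """Samples x regions feature matrix (optionally dropping chrX).

        With ``probe_weighted`` each region is scaled by sqrt(n_markers),
        so Euclidean distances equal those between the probe-resolution
        expansions of the reduced profiles (the reduction preserves probe
        continuity, so a region speaks with the weight of its probes).
        """
        keep = np.ones(len(self.regions), dtype=bool)
        if exclude_chrX:
            keep = (self.regions["chrom"] != "chrX").to_numpy()
        vals = self.values[keep, :]
        if probe_weighted:
            w = np.sqrt(self.regions.loc[keep, "n_markers"].to_numpy(dtype=float))
            vals = vals * w[:, None]
        return vals.T.copy()


def reduce_to_regions(
    profiles: list[SegmentedProfile], probe_map: pd.DataFrame
) -> ReducedMatrix:
    """Reduce a cohort to the union of all samples' breakpoints."""
    chroms = probe_map["chrom"].to_numpy()
    starts_bp = probe_map["start"].to_numpy()
    ends_bp = probe_map["end"].to_numpy()
    arms = probe_map["arm"].to_numpy() if "arm" in probe_map.columns else None

    bounds: dict[str, set[int]] = {}
    for prof in profiles:
        for s in prof.segments:
            bounds.setdefault(s.chrom, set()).update((s.start, s.end))

    region_rows = []
    region_slices = []
    for chrom in pd.unique(chroms):
        bps = sorted(bounds[chrom])
        for a, b in zip(bps, bps[1:]):
            region_rows.append(
                (
                    chrom,
                    a,
                    b,
                    int(starts_bp[a]),
                    int(ends_bp[b - 1]),
                    b - a,
                    arms[a] if arms is not None else "",
                )
            )
            region_slices.append((a, b))
    regions = pd.DataFrame(
        region_rows,
        columns=["chrom", "start_idx", "end_idx", "start", "end", "n_markers", "arm"],
    )

    region_starts = regions["start_idx"].to_numpy()
    values = np.empty((len(regions), len(profiles)))
    for s_i, prof in enumerate(profiles):
        for seg in prof.segments:
            lo = int(np.searchsorted(region_starts, seg.start))
            hi = int(np.searchsorted(region_starts, seg.end))
            values[lo:hi, s_i] = seg.seg_mean
    return ReducedMatrix(regions, values, [p.sample_id for p in profiles])


# --- SEG interop ------------------------------------------------------------

def profiles_to_seg(profiles: list[SegmentedProfile], probe_map: pd.DataFrame) -> pd.DataFrame:
    """Internal segments -> SEG frame (bp, 0-based half-open)."""
    starts = probe_map["start"].to_numpy()
    ends = probe_map["end"].to_numpy()
    rows = []
    for prof in profiles:
        for s in sorted(prof.segments, key=lambda s: s.start):
            rows.append(
                (
                    prof.sample_id,
                    s.chrom,
                    int(starts[s.start]),
                    int(ends[s.end - 1]),
                    s.n_markers,
                    s.seg_mean,
                )
            )
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_markers", "seg_mean"]
    )


def seg_to_profiles(seg: pd.DataFrame, probe_map: pd.DataFrame) -> list[SegmentedProfile]:
    """SEG frame (bp, 0-based half-open) -> internal profiles."""
    chroms = probe_map["chrom"].to_numpy()
    starts = probe_map["start"].to_numpy()
    profiles = []
    for sample, grp in seg.groupby("sample", sort=False):
        segments = []
        for row in grp.itertuples(index=False):
            chrom = normalize_chrom(row.chrom)
            mask = chroms == chrom
            idx = np.flatnonzero(mask)
            local = starts[idx]
            a = int(idx[0] + np.searchsorted(local, row.start))
            b = int(idx[0] + np.searchsorted(local, row.end))
            segments.append(Segment(chrom, a, b, float(row.seg_mean)))
        profiles.append(SegmentedProfile(str(sample), sorted(segments, key=lambda s: s.start)))
    return profiles
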