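"""Per-sample MAD-scaled gain/loss calling on segmented profiles.

The dynamic threshold is a scaled median absolute deviation of the sample's
segment means: segments whose mean exceeds +scale*MAD are called gain,
segments below -scale*MAD are called loss (strict inequalities).  The MAD
is computed over segment means, unweighted by segment size, centered at
their median, without the 1.4826 normal-consistency constant — the literal
"MAD across all segments" reading; the centering and the probe-level
alternative are exposed as options.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segment import SegmentedProfile

log = logging.getLogger("cnaprog.calling")

DEFAULT_MAD_SCALE = 1.11


def mad_threshold(
    profile: SegmentedProfile,
    scale: float = DEFAULT_MAD_SCALE,
    center: str = "median",
    probe_values: np.ndarray | None = None,
) -> tuple[float, float]:
    """Symmetric (gain_thr, loss_thr) for one sample.

    ``center='zero'`` centers the absolute deviations at 0 instead of the
    median; passing ``probe_values`` computes the MAD over probe-level
    ratios instead of segment means.  A single-segment profile yields MAD 0
    (every nonzero segment would be called) and logs a warning.
    """
    if not profile.segments:
        raise ValueError("profile has no segments")
    if probe_values is not None:
        vals = np.asarray(probe_values, dtype=float)
    else:
        vals = np.array([s.seg_mean for s in profile.segments])
    if len(vals) == 1:
        log.warning(
            "sample %s: degenerate single-segment profile, MAD threshold is 0",
            profile.sample_id,
        )
    m = np.median(vals) if center == "median" else 0.0
    mad = float(np.median(np.abs(vals - m)))
    thr = scale * mad
    return thr, thr


@dataclass
class CallMatrix:
    """Probe x sample gain/loss/neutral calls in {-1, 0, +1}."""

    calls: pd.DataFrame
    thresholds: dict[str, tuple[float, float]]


def call_segments(profile: SegmentedProfile, gain_thr: float, loss_thr: float) -> list[int]:
    out = []
    for s in profile.segments:
        if s.seg_mean > gain_thr:
            out.append(1)
        elif s.seg_mean < -loss_thr:
            out.append(-1)
        else:
            out.append(0)
    return out


def call_alterations(
    profiles: list[SegmentedProfile],
    probe_map: pd.DataFrame,
    mask=None,
    scale: float = DEFAULT_MAD_SCALE,
    center: str = "median",
    log2: pd.DataFrame | None = None,
) -> CallMatrix:
    """Per-probe calls for a segmented cohort.

    If a CNV mask is supplied, masked probes are dropped from the output
    (they should normally be removed before segmentation; this is the
    belt-and-braces path for externally segmented data).  Passing ``log2``
    switches the MAD basis from segment means to probe-level ratios (the
    alternative reading; the probe-level spread is insensitive to how many
    segments a genome happens to have, so a quiet genome is not called all
    over).
    """
    n_probes = len(probe_map)
    mat = np.zeros((n_probes, len(profiles)), dtype=np.int8)
    thresholds: dict[str, tuple[float, float]] = {}
    for s_i, prof in enumerate(profiles):
        pv = log2[prof.sample_id].to_numpy() if log2 is not None else None
        g, l = mad_threshold(prof, scale=scale, center=center, probe_values=pv)
        thresholds[prof.sample_id] = (g, l)
        seg_calls = call_segments(prof, g, l)
        for seg, c in zip(prof.segments, seg_calls):
            if c:
                mat[seg.start : seg.end, s_i] = c
    calls = pd.DataFrame(
        mat, index=probe_map["probe_id"].to_numpy(), columns=[p.sample_id for p in profiles]
    )
    calls.index.name = "probe_id"
    if mask is not None and len(mask):
        calls = calls.loc[~calls.index.isin(set(mask.probe_ids))]
    return CallMatrix(calls, thresholds)


def write_calls(cm: CallMatrix, calls_path, thresholds_path) -> None:
    import json

    cm.calls.to_csv(calls_path, sep="\t", index_label="probe_id")
    with open(thresholds_path, "w") as fh:
        json.dump({k: list(v) for k, v in cm.thresholds.items()}, fh, indent=1)
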