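"""Synthetic aCGH cohort generator.

Generates probe-level log2(tumor/reference) matrices with the statistical
structure the downstream analysis assumes: two latent prognostic subgroups,
shared and subgroup-specific copy-number events, Gaussian probe noise, a
single attenuation scalar standing in for tumor-cell fraction, and
exponential survival times coupled to subgroup.

The generative model is deliberately minimal:

    log2[p, s] = attenuation * sum_{events carried by s covering p} signed magnitude
                 + N(0, noise_sd^2)

Carrier status is Bernoulli per (event, sample) with a subgroup-dependent
probability.  Overlapping same-kind events on one sample are summed (the
additive model's natural behavior), not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genome import (
    HG18_CHROMOSOMES,
    GenomeModel,
    build_probe_map,
    default_genome,
    normalize_chrom,
)

DEFAULT_FOCAL_MAGNITUDE = 0.8
DEFAULT_BROAD_MAGNITUDE = 0.35

#: Default genome shrink factor for desk-scale cohorts (1/20 of hg18).
DEFAULT_GENOME_SCALE = 0.05


@dataclass(frozen=True)
class EventSpec:
    """One recurrent copy-number event.

    ``magnitude`` is the expected |log2| shift before attenuation; its sign
    is applied from ``kind``.  ``carrier_prob_by_subgroup`` gives the
    Bernoulli carrier probability per latent subgroup.
    """

    chrom: str
    start: int
    end: int
    kind: str  # "gain" | "loss"
    magnitude: float
    scope: str  # "broad" | "focal"
    carrier_prob_by_subgroup: tuple[float, ...]
    label: str = ""
    #: events sharing a non-empty mutex_group are mutually exclusive within
    #: a sample (e.g. an arm is gained or lost, never both)
    mutex_group: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start >= self.end:
            raise ValueError(f"{self.label or self.chrom}: start must be < end")
        if self.kind not in ("gain", "loss"):
            raise ValueError(f"kind must be 'gain' or 'loss', got {self.kind!r}")
        if self.scope not in ("broad", "focal"):
            raise ValueError(f"scope must be 'broad' or 'focal', got {self.scope!r}")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be > 0")
        for p in self.carrier_prob_by_subgroup:
            if not 0 <= p <= 1:
                raise ValueError("carrier probabilities must lie in [0, 1]")

    @property
    def signed_magnitude(self) -> float:
        return self.magnitude if self.kind == "gain" else -self.magnitude

    @property
    def is_discriminating(self) -> bool:
        probs = self.carrier_prob_by_subgroup
        return len(set(probs)) > 1

    def validate_scope(self, genome: GenomeModel) -> None:
        """Focal events must span < 50% of their arm, broad events >= 50%."""
        chrom = genome[self.chrom]
        arm = chrom.arm_of(self.start)
        lo, hi = chrom.arm_bounds(arm)
        frac = (min(self.end, hi) - max(self.start, lo)) / (hi - lo)
        if self.scope == "focal" and frac >= 0.5:
            raise ValueError(f"{self.label or self.chrom}: focal event spans {frac:.0%} of arm")
        if self.scope == "broad" and frac < 0.5:
            raise ValueError(f"{self.label or self.chrom}: broad event spans {frac:.0%} of arm")


@dataclass(frozen=True)
class SurvivalConfig:
    """Exponential survival per subgroup with independent uniform censoring.

    Medians are in months; event times are Exp(rate = ln2 / median).  The
    censoring time is Uniform(0, u) with u solved so the expected censoring
    fraction over the subgroup mixture matches the configured rate.
    """

    pfs_median_by_subgroup: tuple[float, ...] = (4.4, 11.0)
    os_median_by_subgroup: tuple[float, ...] = (15.4, 38.5)
    pfs_censoring: float = 0.28
    os_censoring: float = 0.59

    def __post_init__(self) -> None:
        for m in (*self.pfs_median_by_subgroup, *self.os_median_by_subgroup):
            if m <= 0:
                raise ValueError("survival medians must be > 0")
        for c in (self.pfs_censoring, self.os_censoring):
            if not 0 <= c < 1:
                raise ValueError("censoring rate must lie in [0, 1)")


@dataclass(frozen=True)
class CohortConfig:
    seed: int
    n_samples: int = 72
    subgroup_proportions: tuple[float, ...] = (0.5, 0.5)
    events: tuple[EventSpec, ...] = ()
    noise_sd: float = 0.15
    attenuation: float = 0.8
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    genome_scale: float = DEFAULT_GENOME_SCALE
    probe_spacing: int = 21_700
    include_x: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.attenuation <= 1:
            raise ValueError("attenuation must lie in (0, 1]")
        if abs(sum(self.subgroup_proportions) - 1.0) > 1e-9:
            raise ValueError("subgroup proportions must sum to 1")
        n_groups = len(self.subgroup_proportions)
        for e in self.events:
            if len(e.carrier_prob_by_subgroup) != n_groups:
                raise ValueError(
                    f"event {e.label or e.chrom}: carrier probabilities for "
                    f"{len(e.carrier_prob_by_subgroup)} subgroups, expected {n_groups}"
                )

    def build_genome(self) -> GenomeModel:
        return default_genome(
            scale=self.genome_scale,
            probe_spacing=self.probe_spacing,
            include_x=self.include_x,
        )


@dataclass
class SimulatedCohort:
    genome: GenomeModel
    probe_map: pd.DataFrame
    log2: pd.DataFrame  # probes x samples, index = probe_id
    truth_labels: pd.Series  # sample -> subgroup index
    truth_events: pd.DataFrame  # events x samples 0/1 carrier matrix
    clinical: pd.DataFrame
    config: CohortConfig

    @property
    def sample_ids(self) -> list[str]:
        return list(self.log2.columns)


def _assign_subgroups(n: int, proportions: tuple[float, ...], rng: np.random.Generator) -> np.ndarray:
    """Deterministic subgroup counts (largest-remainder), randomized order."""
    raw = np.array(proportions) * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    labels = np.repeat(np.arange(len(proportions)), counts)
    rng.shuffle(labels)
    return labels


def _censoring_upper(rates: np.ndarray, weights: np.ndarray, target: float) -> float:
    """Solve for u with C ~ U(0, u) so E[P(C < T)] over the mixture = target."""
    if target <= 0:
        return math.inf

    def cens(u: float) -> float:
        lam = rates * u
        return float(np.sum(weights * (1 - np.exp(-lam)) / lam))

    return brentq(lambda u: cens(u) - target, 1e-9, 1e9)


def simulate_survival(
    labels: np.ndarray | pd.Series,
    survival: SurvivalConfig,
    seed: int,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate PFS/OS with subgroup-blind covariates.

    Returns a clinical table: sample, pfs_months, pfs_event, os_months,
    os_event, age, stage, optimal_cytoreduction.  Covariates are drawn
    independently of subgroup (they carry no prognostic signal here).
    """
    labels = np.asarray(labels)
    n = len(labels)
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    cols: dict[str, np.ndarray | list] = {"sample": list(sample_ids)}
    for prefix, medians, cens_rate in (
        ("pfs", survival.pfs_median_by_subgroup, survival.pfs_censoring),
        ("os", survival.os_median_by_subgroup, survival.os_censoring),
    ):
        rates = np.array([math.log(2) / m for m in medians])
        # subgroups beyond the configured medians reuse the last median
        idx = np.minimum(labels, len(rates) - 1)
        t = rng.exponential(1.0 / rates[idx])
        if cens_rate > 0:
            w = np.bincount(idx, minlength=len(rates)) / n
            u = _censoring_upper(rates, w, cens_rate)
            c = rng.uniform(0, u, size=n)
            event = (t <= c).astype(int)
            time = np.minimum(t, c)
        else:
            event = np.ones(n, dtype=int)
            time = t
        cols[f"{prefix}_months"] = time
        cols[f"{prefix}_event"] = event

    cols["age"] = np.clip(rng.normal(61, 10, size=n), 37, 90).round(1)
    cols["stage"] = rng.choice(["II", "III", "IV"], size=n, p=[0.07, 0.60, 0.33])
    cols["optimal_cytoreduction"] = rng.binomial(1, 0.89, size=n)
    return pd.DataFrame(cols)


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort; deterministic given config.seed."""
    genome = config.build_genome()
    for e in config.events:
        e.validate_scope(genome)
    probe_map = build_probe_map(genome)
    n_probes, n_samples = len(probe_map), config.n_samples
    root = np.random.SeedSequence(config.seed)
    ss_labels, ss_carriers, ss_noise, ss_surv = root.spawn(4)

    labels = _assign_subgroups(
        n_samples, config.subgroup_proportions, np.random.default_rng(ss_labels)
    )
    rng_carriers = np.random.default_rng(ss_carriers)
    carriers = np.zeros((len(config.events), n_samples), dtype=np.int8)
    group_members: dict[str, list[int]] = {}
    for i, e in enumerate(config.events):
        if e.mutex_group:
            group_members.setdefault(e.mutex_group, []).append(i)
    drawn_groups: set[str] = set()
    for i, e in enumerate(config.events):
        if not e.mutex_group:
            probs = np.array(e.carrier_prob_by_subgroup)[labels]
            carriers[i] = rng_carriers.random(n_samples) < probs
        elif e.mutex_group not in drawn_groups:
            drawn_groups.add(e.mutex_group)
            idxs = group_members[e.mutex_group]
            P = np.stack(
                [np.array(config.events[j].carrier_prob_by_subgroup)[labels] for j in idxs]
            )
            if (P.sum(axis=0) > 1 + 1e-9).any():
                raise ValueError(
                    f"mutex group {e.mutex_group!r}: carrier probabilities exceed 1"
                )
            u = rng_carriers.random(n_samples)
            cum = np.cumsum(P, axis=0)
            lower = np.vstack([np.zeros(n_samples), cum[:-1]])
            for rank, j in enumerate(idxs):
                carriers[j] = (u >= lower[rank]) & (u < cum[rank])

    signal = np.zeros((n_probes, n_samples))
    chrom_arr = probe_map["chrom"].to_numpy()
    start_arr = probe_map["start"].to_numpy()
    end_arr = probe_map["end"].to_numpy()
    mid_arr = (start_arr + end_arr) // 2
    for i, e in enumerate(config.events):
        # a probe is covered when its midpoint falls inside the event, so
        # abutting events (e.g. p- and q-arm aneuploidies meeting at the
        # centromere) never double-cover a junction probe
        in_event = (chrom_arr == e.chrom) & (mid_arr >= e.start) & (mid_arr < e.end)
        signal[np.ix_(in_event, carriers[i].astype(bool))] += e.signed_magnitude

    rng_noise = np.random.default_rng(ss_noise)
    values = config.attenuation * signal
    if config.noise_sd > 0:
        values = values + rng_noise.normal(0, config.noise_sd, size=values.shape)

    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    log2 = pd.DataFrame(values, index=probe_map["probe_id"].to_numpy(), columns=sample_ids)
    log2.index.name = "probe_id"

    surv_seed = int(np.random.default_rng(ss_surv).integers(2**31 - 1))
    clinical = simulate_survival(labels, config.survival, surv_seed, sample_ids)

    event_labels = [e.label or f"{e.kind}_{e.chrom}:{e.start}-{e.end}" for e in config.events]
    truth_events = pd.DataFrame(carriers, index=event_labels, columns=sample_ids)
    truth_labels = pd.Series(labels, index=sample_ids, name="subgroup")
    return SimulatedCohort(
        genome=genome,
        probe_map=probe_map,
        log2=log2,
        truth_labels=truth_labels,
        truth_events=truth_events,
        clinical=clinical,
        config=config,
    )


# --- the reference scenario -------------------------------------------------

# hg18-scale intervals of the eight subgroup-discriminating regions plus the
# four most frequent shared alterations of high-grade serous ovarian tumors.
# The 17p12 / 17p11.2 pair is trimmed to keep a >= 2.2 Mb neutral gap so the
# two adjacent losses remain separable after desk-scale genome shrinking.
_DISCRIMINATING = [
    # (label, chrom, start, end, kind, carried-by subgroup index)
    ("8p21.3", "chr8", 22_388_473, 25_606_748, "loss", 1),
    # subtelomeric; runs to the chromosome start so no sub-minimum edge
    # sliver is left to dilute carrier segments
    ("8p23.2", "chr8", 0, 5_781_946, "loss", 1),
    ("12p12.1", "chr12", 16_803_022, 25_998_952, "gain", 0),
    ("17p11.2", "chr17", 18_300_000, 21_720_090, "loss", 1),
    ("17p12", "chr17", 10_689_461, 16_100_000, "loss", 1),
    ("19q12", "chr19", 34_794_890, 35_592_893, "gain", 0),
    ("20q11.21", "chr20", 29_363_673, 29_773_184, "gain", 0),
    ("20q13.12", "chr20", 42_510_865, 45_356_897, "gain", 0),
]

_SHARED = [
    ("3q26.2", "chr3", 170_088_444, 170_608_075, "gain", 0.75),
    ("8q24.21", "chr8", 128_870_582, 129_868_380, "gain", 0.75),
    ("16q24.2", "chr16", 86_172_468, 87_009_930, "loss", 0.78),
    ("22q13.33", "chr22", 48_814_623, 49_204_003, "loss", 0.78),
]

#: Minimum full-scale event width so every implant spans >= ~6 probes after
#: 1/20 genome scaling at 21.7 kb spacing.
_MIN_EVENT_WIDTH = 3_000_000

# Broad background structure.  High-grade serous genomes carry pervasive
# arm-level alteration; the scenario models every autosomal arm as being in
# one of three states per sample -- gained, lost, or neutral (mutually
# exclusive, single-copy amplitudes).  On "signature" arms the gain/loss
# balance is subgroup-dependent (the aneuploidy landscape that separates
# the subgroups); on neutral arms both kinds occur at an equal passenger
# rate in both subgroups.  This dense arm-level background gives the
# significance scan's within-sample permutation null a realistic
# per-sample aberration burden: recurrent whole arms sit at the null's
# centre rather than above it, and only the focal implants (and strongly
# tilted signature arms) rise clear of it.  On arms hosting focal events
# the arm states cover only the remainder outside the focal windows, so
# focal markers do not ride on an arm-level baseline.
_TILTED_GAIN_ARMS = [  # gains favored in subgroup 0 (poor outcome)
    "1q", "2p", "3p", "5p", "6p", "7q", "9p", "10p", "11q", "12q", "13q",
    "14q", "16p", "19p", "20p",
]
_TILTED_LOSS_ARMS = [  # losses favored in subgroup 1 (good outcome)
    "1p", "2q", "4p", "4q", "5q", "6q", "7p", "9q", "10q", "11p", "15q",
    "17q", "18p", "18q", "21q",
]
#: Minimum full-scale width of a passenger piece (same resolution floor as
#: the focal implants).
_MIN_PASSENGER_WIDTH = 3_000_000

#: Buffer between a focal window and the surrounding passenger pieces, so
#: segmentation breakpoint jitter (about one probe) can never bridge a
#: passenger segment into a focal marker.
_PASSENGER_BUFFER = 1_500_000


#: Focal windows closer than this to an arm boundary are snapped onto it,
#: so no sub-minimum sliver (which the small-segment merge would fold into
#: the event, diluting carrier amplitudes) is left at the edge.
_EDGE_MARGIN = 2_200_000


def _expand_interval(
    genome_full: GenomeModel, chrom: str, start: int, end: int, min_width: int
) -> tuple[int, int]:
    """Expansion to min_width, clipped to the containing arm.

    A window ending sub-margin from a telomere is snapped onto it (no
    orphan sliver for the small-segment merge to fold into the event); a
    window sub-margin from the centromere is pushed away instead, so the
    event never abuts the neighboring arm's events, which would tempt the
    segmenter into fusing the two amplitude levels.
    """
    c = genome_full[chrom]
    arm = c.arm_of(start)
    lo, hi = c.arm_bounds(arm)
    s, e = start, end
    if e - s < min_width:
        mid = (s + e) // 2
        s = max(lo, mid - min_width // 2)
        e = min(hi, s + min_width)
        s = max(lo, e - min_width)
    if arm == "p":
        if s - lo < _EDGE_MARGIN:  # telomere side
            s = lo
        if hi - e < _EDGE_MARGIN:  # centromere side
            e = hi - _EDGE_MARGIN
    else:
        if s - lo < _EDGE_MARGIN:  # centromere side
            s = lo + _EDGE_MARGIN
            e = max(e, s + min_width)
        if hi - e < _EDGE_MARGIN:  # telomere side
            e = hi
    return s, e


def _arm_bounds_scaled(arm: str, genome_scale: float) -> tuple[str, int, int]:
    chrom = "chr" + arm[:-1]
    length, cen = HG18_CHROMOSOMES[chrom]
    length, cen = int(length * genome_scale), int(cen * genome_scale)
    return (chrom, 0, cen) if arm.endswith("p") else (chrom, cen, length)


def default_reference_scenario(
    seed: int = 1,
    n_samples: int = 72,
    noise_sd: float = 0.15,
    genome_scale: float = DEFAULT_GENOME_SCALE,
    disc_probs: tuple[float, float] = (0.75, 0.15),
    magnitude: float = DEFAULT_FOCAL_MAGNITUDE,
    tilt_main: float = 0.90,
    tilt_cross: float = 0.10,
    passenger_rate: float = 0.40,
    passenger_gain_magnitude: float = 0.55,
    passenger_loss_magnitude: float = 0.60,
) -> CohortConfig:
    """Two-subgroup scenario mirroring the structure of the 72-tumor
    discovery cohort.

    Recurrent focal structure: eight subgroup-discriminating events (gains
    on 12p12.1/19q12/20q11.21/20q13.12 in the poor-outcome subgroup 0,
    losses on 8p21.3/8p23.2/17p11.2/17p12 in the good-outcome subgroup 1)
    plus four shared alterations at 75-78% carrier frequency.  Broad
    structure: every autosomal arm is gained, lost, or neutral per sample
    at single-copy amplitude; signature arms favor one kind in one
    subgroup (``tilt_main`` there, ``tilt_cross`` for the opposite kind,
    plain passenger behavior in the other subgroup), all other arms use
    ``passenger_rate`` for both kinds in both subgroups.

    Event coordinates are hg18-scale intervals mapped proportionally onto
    the (optionally shrunk) synthetic genome.
    """
    full = default_genome(scale=1.0)
    hi, lo = disc_probs
    events = []
    focal_by_arm: dict[str, list[tuple[int, int]]] = {}

    def _arm_name(chrom: str, pos: int) -> str:
        return chrom.removeprefix("chr") + full[chrom].arm_of(pos)

    focal_specs = [
        (label, chrom, start, end, kind, (hi, lo) if grp == 0 else (lo, hi))
        for label, chrom, start, end, kind, grp in _DISCRIMINATING
    ] + [
        (label, chrom, start, end, kind, (p, p))
        for label, chrom, start, end, kind, p in _SHARED
    ]
    for label, chrom, start, end, kind, probs in focal_specs:
        s, e = _expand_interval(full, chrom, start, end, _MIN_EVENT_WIDTH)
        focal_by_arm.setdefault(_arm_name(chrom, s), []).append((s, e))
        events.append(
            EventSpec(
                chrom=chrom,
                start=int(s * genome_scale),
                end=int(e * genome_scale),
                kind=kind,
                magnitude=magnitude,
                scope="focal",
                carrier_prob_by_subgroup=probs,
                label=label,
            )
        )

    # arm states everywhere (gain/loss mutually exclusive per piece); on
    # focal-event arms only the remainder pieces outside the buffered focal
    # windows, and only pieces wide enough to segment cleanly
    r = passenger_rate
    for chrom_name, (length, cen) in HG18_CHROMOSOMES.items():
        if chrom_name == "chrX":
            continue
        for arm_lo, arm_hi, arm_suffix in ((0, cen, "p"), (cen, length, "q")):
            arm = chrom_name.removeprefix("chr") + arm_suffix
            if arm in _TILTED_GAIN_ARMS:
                tag = "signature"
                gain_probs, loss_probs = (tilt_main, r), (tilt_cross, r)
            elif arm in _TILTED_LOSS_ARMS:
                tag = "signature"
                gain_probs, loss_probs = (r, tilt_cross), (r, tilt_main)
            else:
                tag = "passenger"
                gain_probs, loss_probs = (r, r), (r, r)
            pieces = [(arm_lo, arm_hi)]
            for f_s, f_e in sorted(focal_by_arm.get(arm, [])):
                fs, fe = f_s - _PASSENGER_BUFFER, f_e + _PASSENGER_BUFFER
                nxt = []
                for ps, pe in pieces:
                    if fs > ps:
                        nxt.append((ps, min(fs, pe)))
                    if fe < pe:
                        nxt.append((max(fe, ps), pe))
                pieces = nxt
            pieces = [p for p in pieces if p[1] - p[0] >= _MIN_PASSENGER_WIDTH]
            for i, (ps, pe) in enumerate(pieces):
                # a piece can be sub-arm wide; it is still landscape, and a
                # "broad" scope would violate the arm-fraction invariant
                scope = "broad" if (pe - ps) >= 0.5 * (arm_hi - arm_lo) else "focal"
                for kind, mag, probs in (
                    ("gain", passenger_gain_magnitude, gain_probs),
                    ("loss", passenger_loss_magnitude, loss_probs),
                ):
                    events.append(
                        EventSpec(
                            chrom=chrom_name,
                            start=int(ps * genome_scale),
                            end=int(pe * genome_scale),
                            kind=kind,
                            magnitude=mag,
                            scope=scope,
                            carrier_prob_by_subgroup=probs,
                            label=f"{tag}_{kind}_{arm}.{i}",
                            mutex_group=f"arm_{arm}.{i}",
                        )
                    )
    return CohortConfig(
        seed=seed,
        n_samples=n_samples,
        events=tuple(events),
        noise_sd=noise_sd,
        genome_scale=genome_scale,
    )


def discriminating_events(config: CohortConfig) -> list[EventSpec]:
    """The named focal subgroup-discriminating implants (the marker truth).

    Broad subgroup-tilted aneuploidy is background landscape, not a named
    discriminating locus, and is excluded here.
    """
    return [e for e in config.events if e.is_discriminating and e.scope == "focal"]


def with_seed(config: CohortConfig, seed: int) -> CohortConfig:
    return replace(config, seed=seed)
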