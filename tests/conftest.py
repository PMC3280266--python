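import numpy as np
import pandas as pd
import pytest

from cnaprog.genome import build_genome
from cnaprog.simulate import CohortConfig, EventSpec


@pytest.fixture
def tiny_genome():
    """Two small chromosomes (200 + 100 probes) for fast segmentation tests."""
    table = {
        "chr1": (200 * 21_700, 100 * 21_700),
        "chr2": (100 * 21_700, 40 * 21_700),
    }
    return build_genome(table)


def small_cohort_config(
    seed,
    n_samples=6,
    noise_sd=0.1,
    events=(),
    genome_scale=0.002,
    attenuation=1.0,
):
    """Down-scaled cohort (~280 probes over 23 chromosomes)."""
    return CohortConfig(
        seed=seed,
        n_samples=n_samples,
        events=tuple(events),
        noise_sd=noise_sd,
        attenuation=attenuation,
        genome_scale=genome_scale,
    )


def gain_event(chrom="chr1", start=0, end=100_000, magnitude=0.8,
               probs=(1.0, 0.0), scope="focal", label="gain"):
    return EventSpec(
        chrom=chrom, start=start, end=end, kind="gain", magnitude=magnitude,
        scope=scope, carrier_prob_by_subgroup=probs, label=label,
    )


def brute_force_best_arc(x):
    """Independent oracle for the circular split statistic: naive loops
    over all arcs [i, j), computing mean differences directly.  Suffix
    arcs (j = n) are skipped - the complement of [i, n) is the prefix arc
    [0, i), already enumerated, so each partition is scored once."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    best = (-1.0, 0, 1)
    for i in range(n):
        for j in range(i + 1, n):
            arc = x[i:j]
            comp = np.concatenate([x[:i], x[j:]])
            k = len(arc)
            u = abs(arc.mean() - comp.mean()) / np.sqrt(1.0 / k + 1.0 / (n - k))
            if u > best[0] + 1e-15:
                best = (u, i, j)
    return best[1], best[2], best[0]


def toy_probe_map(n_probes, chrom="chr1", spacing=1000):
    starts = np.arange(n_probes) * spacing
    return pd.DataFrame(
        {
            "probe_id": [f"p{i:04d}" for i in range(n_probes)],
            "chrom": chrom,
            "start": starts,
            "end": starts + spacing,
            "arm": ["p" if s < n_probes * spacing // 2 else "q" for s in starts],
        }
    )
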