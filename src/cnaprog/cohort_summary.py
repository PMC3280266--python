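"""Clinical summary arithmetic for aCGH cohort tables.

Holds the published clinical characteristics of the 72-tumor high-grade
serous discovery cohort whose structure the simulator emulates, plus the
small fraction computations a cohort report performs on such counts.
"""

from __future__ import annotations

#: Clinical characteristics of the discovery cohort (counts of patients).
DISCOVERY_COHORT = {
    "n": 72,
    "stage": {"II": 5, "III": 43, "IV": 24},
    "grade": {"2": 5, "3": 67},
    "platinum_sensitive": 42,
    "platinum_assessable": 70,  # 2 of 72 not assessable
    "optimal_cytoreduction": 64,
    "os_median_months": 38.5,
    "pfs_median_months": 8.0,
}


def advanced_stage_percent(counts: dict = DISCOVERY_COHORT) -> float:
    """Percent of patients presenting at stage III or IV."""
    stage = counts["stage"]
    return 100.0 * (stage["III"] + stage["IV"]) / counts["n"]


def platinum_sensitive_percent(counts: dict = DISCOVERY_COHORT) -> float:
    """Percent platinum sensitive among assessable patients."""
    return 100.0 * counts["platinum_sensitive"] / counts["platinum_assessable"]
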