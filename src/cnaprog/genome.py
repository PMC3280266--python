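"""Synthetic array platform: chromosome model and probe tiling.

The array platform is modelled as a uniform tiling of each chromosome at a
fixed probe spacing (default 21,700 bp, the average spatial resolution of a
105K-feature oligonucleotide CGH array on the hg18 assembly).  Chromosome
lengths and centromere positions are hg18-proportional and can be scaled
down by a common factor so that desk-scale simulations stay small while the
relative geometry of arms and cytoband-scale events is preserved.

Coordinates are 0-based half-open throughout.  chrY is never tiled: the
reference hybridizations are female, so Y carries no usable signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_PROBE_SPACING = 21_700

# (length bp, centromere bp), hg18-proportional.  Centromere positions are
# approximate band boundaries; they only drive p/q arm assignment.
HG18_CHROMOSOMES: dict[str, tuple[int, int]] = {
    "chr1": (247_249_719, 125_000_000),
    "chr2": (242_951_149, 93_300_000),
    "chr3": (199_501_827, 91_000_000),
    "chr4": (191_273_063, 50_400_000),
    "chr5": (180_857_866, 48_400_000),
    "chr6": (170_899_992, 61_000_000),
    "chr7": (158_821_424, 59_900_000),
    "chr8": (146_274_826, 45_600_000),
    "chr9": (140_273_252, 49_000_000),
    "chr10": (135_374_737, 40_200_000),
    "chr11": (134_452_384, 53_700_000),
    "chr12": (132_349_534, 35_800_000),
    "chr13": (114_142_980, 17_900_000),
    "chr14": (106_368_585, 17_600_000),
    "chr15": (100_338_915, 19_000_000),
    "chr16": (88_827_254, 36_600_000),
    "chr17": (78_774_742, 24_000_000),
    "chr18": (76_117_153, 17_200_000),
    "chr19": (63_811_651, 26_500_000),
    "chr20": (62_435_964, 27_500_000),
    "chr21": (46_944_323, 13_200_000),
    "chr22": (49_691_432, 14_700_000),
    "chrX": (154_913_754, 60_600_000),
}

CHROM_ORDER = list(HG18_CHROMOSOMES)


def normalize_chrom(name: str) -> str:
    """Accept both ``19`` and ``chr19`` dialects; normalize to ``chr19``."""
    name = str(name).strip()
    if not name:
        raise ValueError("empty chromosome name")
    if not name.startswith("chr"):
        name = f"chr{name}"
    if name in ("chrY", "chry"):
        raise ValueError("chrY is not part of the platform model")
    return name


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: chromosome length must be > 0")
        if not 0 < self.centromere < self.length:
            raise ValueError(
                f"{self.name}: centromere {self.centromere} outside (0, {self.length})"
            )

    def arm_of(self, pos: int) -> str:
        return "p" if pos < self.centromere else "q"

    def arm_bounds(self, arm: str) -> tuple[int, int]:
        return (0, self.centromere) if arm == "p" else (self.centromere, self.length)


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome set plus probe spacing."""

    chromosomes: tuple[Chromosome, ...]
    probe_spacing: int = DEFAULT_PROBE_SPACING
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("at least one chromosome required")
        if self.probe_spacing <= 0:
            raise ValueError("probe spacing must be > 0")
        object.__setattr__(self, "_index", {c.name: c for c in self.chromosomes})

    def __getitem__(self, name: str) -> Chromosome:
        return self._index[normalize_chrom(name)]

    def __contains__(self, name: str) -> bool:
        return normalize_chrom(name) in self._index

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def n_probes(self) -> int:
        """Closed-form probe count: sum of floor(length / spacing)."""
        return int(sum(c.length // self.probe_spacing for c in self.chromosomes))

    def arm_length(self, chrom: str, arm: str) -> int:
        lo, hi = self[chrom].arm_bounds(arm)
        return hi - lo


def default_genome(
    scale: float = 1.0,
    probe_spacing: int = DEFAULT_PROBE_SPACING,
    include_x: bool = True,
) -> GenomeModel:
    """hg18-proportional genome, optionally shrunk by ``scale``.

    ``scale=0.05`` (1/20) is the desk-scale default used by the cohort
    simulator; ``scale=1`` reproduces the full-resolution platform with
    ~1.3e5 autosomal probes at 21.7 kb spacing.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    chroms = []
    for name, (length, cen) in HG18_CHROMOSOMES.items():
        if name == "chrX" and not include_x:
            continue
        chroms.append(
            Chromosome(name, max(int(length * scale), 1), max(int(cen * scale), 1))
        )
    return GenomeModel(tuple(chroms), probe_spacing)


def build_probe_map(genome: GenomeModel) -> pd.DataFrame:
    """Tile every chromosome at the genome's probe spacing.

    Returns the probe map: columns probe_id, chrom, start, end, arm;
    0-based half-open; each probe's interval is one spacing-wide tiling
    cell.  Probes whose cell would extend past the chromosome end are not
    emitted (count per chromosome = floor(length / spacing)).
    """
    rows = []
    for c in genome.chromosomes:
        n = c.length // genome.probe_spacing
        starts = np.arange(n, dtype=np.int64) * genome.probe_spacing
        for s in starts:
            rows.append((c.name, int(s), int(s) + genome.probe_spacing))
    pm = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    pm.insert(0, "probe_id", [f"p{i:06d}" for i in range(len(pm))])
    pm["arm"] = [
        genome[ch].arm_of(st) for ch, st in zip(pm["chrom"], pm["start"])
    ]
    return pm


def build_genome(
    chrom_table: dict[str, tuple[int, int]] | None = None,
    probe_spacing: int = DEFAULT_PROBE_SPACING,
) -> tuple[GenomeModel, pd.DataFrame]:
    """Construct a genome model plus its probe map from a length table.

    ``chrom_table`` maps chromosome name -> (length, centromere); defaults
    to the full hg18-proportional table (autosomes + X).
    """
    if chrom_table is None:
        genome = default_genome(probe_spacing=probe_spacing)
    else:
        chroms = tuple(
            Chromosome(normalize_chrom(n), int(l), int(c))
            for n, (l, c) in chrom_table.items()
        )
        genome = GenomeModel(chroms, probe_spacing)
    return genome, build_probe_map(genome)


def arm_table(probe_map: pd.DataFrame) -> pd.DataFrame:
    """Per-(chrom, arm) bp extent covered by probes."""
    g = probe_map.groupby(["chrom", "arm"], sort=False).agg(
        start=("start", "min"), end=("end", "max"), n_probes=("probe_id", "size")
    )
    g["length"] = g["end"] - g["start"]
    return g.reset_index()
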