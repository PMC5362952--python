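"""Genome coordinate model: chromosomes, arm units, and the bin grid.

Arm-level dosage analysis runs on fixed-width bins tiling each chromosome.
Every bin belongs to exactly one *arm unit*: the p or q arm for chromosomes
with a centromere, or the whole chromosome otherwise.  Chromosome Y is
always a single unit — it is lost as a whole, so arm resolution adds
nothing and would only dilute the signal.

Expected normalized-coverage baselines are sex-aware:

==========  ======  ======
unit        male    female
==========  ======  ======
autosome    1.0     1.0
chrX arm    0.5     1.0
chrY        0.5     absent
==========  ======  ======
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

# GRCh37 chromosome lengths and approximate centromere midpoints (bp).
# chrY carries no centromere entry: it is modelled as one unit.
_HUMAN_CHROMS: tuple[tuple[str, int, int | None], ...] = (
    ("chr1", 249_250_621, 125_000_000),
    ("chr2", 243_199_373, 93_300_000),
    ("chr3", 198_022_430, 91_000_000),
    ("chr4", 191_154_276, 50_400_000),
    ("chr5", 180_915_260, 48_400_000),
    ("chr6", 171_115_067, 61_000_000),
    ("chr7", 159_138_663, 59_900_000),
    ("chr8", 146_364_022, 45_600_000),
    ("chr9", 141_213_431, 49_000_000),
    ("chr10", 135_534_747, 40_200_000),
    ("chr11", 135_006_516, 53_700_000),
    ("chr12", 133_851_895, 35_800_000),
    ("chr13", 115_169_878, 17_900_000),
    ("chr14", 107_349_540, 17_600_000),
    ("chr15", 102_531_392, 19_000_000),
    ("chr16", 90_354_753, 36_600_000),
    ("chr17", 81_195_210, 24_000_000),
    ("chr18", 78_077_248, 17_200_000),
    ("chr19", 59_128_983, 26_500_000),
    ("chr20", 63_025_520, 27_500_000),
    ("chr21", 48_129_895, 13_200_000),
    ("chr22", 51_304_566, 14_700_000),
    ("chrX", 155_270_560, 60_600_000),
    ("chrY", 59_373_566, None),
)

DEFAULT_BIN_SIZE = 5000
DEFAULT_SCALE = 10


def _arm_label(chrom: str, arm: str | None) -> str:
    """'chr3' + 'p' -> '3p'; whole-chromosome units keep the chrom name."""
    if arm is None:
        return chrom
    stem = chrom[3:] if chrom.startswith("chr") else chrom
    return f"{stem}{arm}"


@dataclass(frozen=True)
class GenomeModel:
    """Immutable bin grid plus arm bookkeeping.

    ``bins`` is a DataFrame with columns (chrom, start, end, arm) in
    0-based half-open coordinates, sorted by chromosome (input order) and
    start, one row per bin.
    """

    bin_size: int
    chromosomes: tuple[tuple[str, int], ...]
    centromeres: Mapping[str, int | None]
    bins: pd.DataFrame

    @cached_property
    def _arm_map(self) -> dict[str, tuple[str, np.ndarray]]:
        """arm -> (chrom, positional bin indices), in genome order."""
        out: dict[str, tuple[str, np.ndarray]] = {}
        arms = self.bins["arm"].to_numpy()
        chroms = self.bins["chrom"].to_numpy()
        for arm in dict.fromkeys(arms):
            idx = np.flatnonzero(arms == arm)
            out[arm] = (chroms[idx[0]], idx)
        return out

    @property
    def arms(self) -> list[str]:
        """Arm units in genome order."""
        return list(self._arm_map)

    def chrom_of_arm(self, arm: str) -> str:
        try:
            return self._arm_map[arm][0]
        except KeyError:
            raise KeyError(f"unknown arm unit: {arm!r}") from None

    def arm_bin_index(self, arm: str) -> np.ndarray:
        """Positional indices (into ``bins``) of the bins of one arm."""
        if arm not in self._arm_map:
            raise KeyError(f"unknown arm unit: {arm!r}")
        return self._arm_map[arm][1]

    def baseline(self, arm: str, sex: str) -> float:
        """Expected normalized coverage of ``arm`` in a sample of ``sex``.

        Returns NaN for units absent from the karyotype (chrY in females).
        """
        if sex not in SEXES:
            raise ValueError(f"unknown sex label: {sex!r}")
        chrom = self.chrom_of_arm(arm)
        if chrom == "chrY":
            return 0.5 if sex == MALE else float("nan")
        if chrom == "chrX":
            return 0.5 if sex == MALE else 1.0
        return 1.0

    def arms_for_sex(self, sex: str) -> list[str]:
        """Arm units with a defined baseline for this sex (the tested units)."""
        return [a for a in self.arms if np.isfinite(self.baseline(a, sex))]

    def autosomal_mask(self) -> np.ndarray:
        return ~self.bins["chrom"].isin(("chrX", "chrY")).to_numpy()

    def n_bins(self) -> int:
        return len(self.bins)


def build_genome(config: Mapping) -> GenomeModel:
    """Build the bin grid from a config mapping.

    ``config`` needs ``bin_size`` and ``chromosomes``, a sequence of
    mappings with ``name``, ``length`` and optional ``centromere``.  Bins
    tile each chromosome from 0 in ``bin_size`` steps; a trailing partial
    bin is dropped.  A bin straddling the centromere is assigned to the q
    arm (assignment by bin end).
    """
    bin_size = int(config.get("bin_size", DEFAULT_BIN_SIZE))
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    chrom_specs: Sequence[Mapping] = config["chromosomes"]
    if not chrom_specs:
        raise ValueError("no chromosomes in genome config")

    chroms: list[tuple[str, int]] = []
    centromeres: dict[str, int | None] = {}
    frames: list[pd.DataFrame] = []
    for spec in chrom_specs:
        name = str(spec["name"])
        length = int(spec["length"])
        cen = spec.get("centromere")
        cen = None if cen is None else int(cen)
        if length < 2 * bin_size:
            raise ValueError(
                f"{name}: length {length} shorter than two bins ({2 * bin_size})"
            )
        if name == "chrY":
            cen = None  # one unit, always
        if cen is not None and not (0 < cen < length):
            raise ValueError(f"{name}: centromere {cen} outside chromosome")
        n = length // bin_size
        starts = np.arange(n, dtype=np.int64) * bin_size
        ends = starts + bin_size
        if cen is None:
            arm = np.full(n, _arm_label(name, None), dtype=object)
        else:
            arm = np.where(ends <= cen, _arm_label(name, "p"), _arm_label(name, "q"))
        frames.append(
            pd.DataFrame({"chrom": name, "start": starts, "end": ends, "arm": arm})
        )
        chroms.append((name, length))
        centromeres[name] = cen

    bins = pd.concat(frames, ignore_index=True)
    return GenomeModel(
        bin_size=bin_size,
        chromosomes=tuple(chroms),
        centromeres=centromeres,
        bins=bins,
    )


def default_genome(scale: int = DEFAULT_SCALE, bin_size: int = DEFAULT_BIN_SIZE) -> GenomeModel:
    """Human-like miniature karyotype: GRCh37 scaled down 1/``scale``.

    The default 1/10 scale with 5 kb bins gives roughly 260-2,500 bins per
    arm unit (~62,000 genome-wide), enough for arm medians to concentrate
    tightly while keeping whole-cohort simulations to seconds.
    """
    config = {
        "bin_size": bin_size,
        "chromosomes": [
            {
                "name": name,
                "length": length // scale,
                "centromere": None if cen is None else cen // scale,
            }
            for name, length, cen in _HUMAN_CHROMS
        ],
    }
    return build_genome(config)
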