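"""Classical quantitative karyotype measures from arm-length tables.

Pre-banding cytogenetics described karyotypes through arm measurements:
the centromeric index (CI, percent of total chromosome length contributed
by the short arm), the long/short arm ratio pinpointing the centromere,
the total haploid chromosome length (THCL) and the fundamental number
(FN, the count of chromosome arms over the diploid complement, bounded by
2 x 2n with equality only for fully bi-armed karyotypes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MONO_ARMED_CI_MAX",
    "ChromosomeArms",
    "centromeric_index",
    "arm_ratio",
    "fundamental_number",
    "total_haploid_length",
    "read_arm_table",
    "karyotype_report",
]

#: Default centromeric-index cutoff (percent) below or at which a chromosome
#: counts as mono-armed (acrocentric/telocentric), Levan-style.
MONO_ARMED_CI_MAX = 12.5


@dataclass(frozen=True)
class ChromosomeArms:
    """Short- and long-arm lengths of one chromosome (µm or Mb)."""

    name: str
    short_arm: float
    long_arm: float

    def __post_init__(self) -> None:
        if self.short_arm < 0:
            raise ValueError("short_arm must be >= 0")
        if self.long_arm < self.short_arm:
            raise ValueError("long_arm must be >= short_arm")
        if self.long_arm <= 0:
            raise ValueError("long_arm must be > 0")

    @property
    def total_length(self) -> float:
        return self.short_arm + self.long_arm

    def morphology(self, mono_armed_ci_max: float = MONO_ARMED_CI_MAX) -> str:
        ci = centromeric_index(self)
        return "mono-armed" if ci <= mono_armed_ci_max else "bi-armed"


def centromeric_index(arms: ChromosomeArms) -> float:
    """CI = 100 * short arm / total chromosome length, in [0, 50]."""
    total = arms.total_length
    if total <= 0:
        raise ValueError("total chromosome length must be > 0")
    return 100.0 * arms.short_arm / total


def arm_ratio(arms: ChromosomeArms) -> float:
    """Long/short arm ratio (>= 1); infinite for telocentrics (short arm 0)."""
    if arms.short_arm == 0:
        return math.inf
    return arms.long_arm / arms.short_arm


def fundamental_number(
    karyotype: Iterable[ChromosomeArms],
    mono_armed_ci_max: float = MONO_ARMED_CI_MAX,
) -> int:
    """Count chromosome arms over the given (diploid) complement.

    Mono-armed chromosomes (CI <= cutoff) contribute one arm, bi-armed two,
    so FN <= 2 x chromosome count, with the deficit equal to the number of
    mono-armed chromosomes.
    """
    fn = 0
    for arms in karyotype:
        fn += 1 if arms.morphology(mono_armed_ci_max) == "mono-armed" else 2
    return fn


def total_haploid_length(karyotype: Sequence[ChromosomeArms]) -> float:
    """THCL: summed chromosome lengths over the haploid set."""
    if not karyotype:
        raise ValueError("THCL of an empty karyotype is undefined")
    return sum(a.total_length for a in karyotype)


def read_arm_table(path: str | Path) -> list[ChromosomeArms]:
    """Read a TSV with columns chromosome, short_arm, long_arm."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ("chromosome", "short_arm", "long_arm")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    return [
        ChromosomeArms(
            name=str(r.chromosome),
            short_arm=float(r.short_arm),
            long_arm=float(r.long_arm),
        )
        for r in df.itertuples(index=False)
    ]


def karyotype_report(
    karyotype: Sequence[ChromosomeArms],
    mono_armed_ci_max: float = MONO_ARMED_CI_MAX,
) -> pd.DataFrame:
    """Per-chromosome metric table: CI, arm ratio, morphology, total length."""
    return pd.DataFrame(
        {
            "chromosome": [a.name for a in karyotype],
            "short_arm": [a.short_arm for a in karyotype],
            "long_arm": [a.long_arm for a in karyotype],
            "total_length": [a.total_length for a in karyotype],
            "centromeric_index": [round(centromeric_index(a), 4) for a in karyotype],
            "arm_ratio": [
                round(arm_ratio(a), 4) if arm_ratio(a) != math.inf else math.inf
                for a in karyotype
            ],
            "morphology": [a.morphology(mono_armed_ci_max) for a in karyotype],
        }
    )
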