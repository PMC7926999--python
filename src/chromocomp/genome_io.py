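"""Reading and validation of soft-masked assemblies and tabular inputs.

Soft-masked FASTA is the primary carrier of repeat annotation here:
lowercase residues mark repeat-derived bases (the Ensembl ``rm`` dump
convention), so case must survive every read/write round-trip bit-exactly.
Chromosome-scale records in large vertebrate assemblies can exceed 350 Mb,
hence :func:`iter_fasta` streams one record at a time.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "MB_PER_PG",
    "LINEAGE_GROUPS",
    "ChromosomeSequence",
    "AssemblyMetadata",
    "ChromosomeTableRow",
    "FastaParseError",
    "FilterResult",
    "read_fasta",
    "iter_fasta",
    "write_fasta",
    "filter_chromosomes",
    "read_chromosome_table",
    "c_value_to_mb",
]

#: Megabases of haploid DNA per picogram (standard genomics conversion).
MB_PER_PG = 978.0

#: Chordate lineage bins used for panel grouping and ordering.
LINEAGE_GROUPS = (
    "tunicate",
    "cephalochordate",
    "lamprey",
    "chondrichthyan",
    "non-teleost fish",
    "teleost",
    "amphibian",
    "reptile",
    "bird",
    "mammal",
)

#: Sequence-name fragments that mark non-chromosomal records in public
#: assemblies (mitochondrion, unplaced scaffolds, ...), matched
#: case-insensitively as substrings.
DEFAULT_NAME_EXCLUDES = (
    "MT",
    "chrM",
    "mito",
    "scaffold",
    "unplaced",
    "unloc",
    "random",
    "contig",
)


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, naming the offending line or record."""


@dataclass(frozen=True)
class ChromosomeSequence:
    """One soft-masked chromosome (or linkage group) of an assembly.

    ``residues`` preserves case exactly: lowercase marks repeat-masked bases.
    """

    id: str
    residues: str
    name: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("chromosome id must be non-empty")
        if len(self.residues) == 0:
            raise ValueError(f"zero-length record {self.id!r}")
        if not self.name:
            object.__setattr__(self, "name", self.id)

    @property
    def length_bp(self) -> int:
        return len(self.residues)

    def length_mb(self, bases_per_mb: float = 1e6) -> float:
        return self.length_bp / bases_per_mb


@dataclass(frozen=True)
class AssemblyMetadata:
    """Species-level assembly descriptors used for panel building."""

    species: str
    lineage_group: str
    assembly_size_mb: float
    n_chromosomes: int
    c_value_pg: float | None = None

    def __post_init__(self) -> None:
        if self.lineage_group not in LINEAGE_GROUPS:
            raise ValueError(
                f"unknown lineage group {self.lineage_group!r}; "
                f"expected one of {LINEAGE_GROUPS}"
            )
        if self.assembly_size_mb <= 0:
            raise ValueError("assembly_size_mb must be > 0")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")


@dataclass(frozen=True)
class ChromosomeTableRow:
    """One row of a pre-computed per-chromosome statistics table."""

    species: str
    chromosome: str
    length_mb: float
    gc_pct: float
    rep_pct: float | None = None

    def __post_init__(self) -> None:
        if self.length_mb <= 0:
            raise ValueError("length_mb must be > 0")
        if not 0.0 <= self.gc_pct <= 100.0:
            raise ValueError("gc_pct must lie in [0, 100]")
        if self.rep_pct is not None and not 0.0 <= self.rep_pct <= 100.0:
            raise ValueError("rep_pct must lie in [0, 100]")


def _check_fasta_head(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno} is not a FASTA header "
                    f"(expected '>'): {line.strip()[:40]!r}"
                )
            return
    raise FastaParseError(f"{path}: empty file")


def iter_fasta(path: str | Path, species: str = "") -> Iterator[ChromosomeSequence]:
    """Stream records of a (soft-masked) FASTA file, one at a time.

    Case and record order are preserved; zero-length records are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_fasta_head(path)
    seen: set[str] = set()
    if not species:
        species = path.stem
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: zero-length record {rec.id!r}")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        yield ChromosomeSequence(
            id=rec.id,
            residues=str(rec.seq),
            name=rec.id,
            species=species,
        )


def read_fasta(path: str | Path, species: str = "") -> list[ChromosomeSequence]:
    """Read every record of a soft-masked FASTA into memory, in file order."""
    return list(iter_fasta(path, species=species))


def write_fasta(
    records: Iterable[ChromosomeSequence],
    path: str | Path,
    line_width: int = 60,
) -> Path:
    """Write records as FASTA, preserving residue case exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            s = rec.residues
            for i in range(0, len(s), line_width):
                fh.write(s[i : i + line_width])
                fh.write("\n")
    return path


@dataclass
class FilterResult:
    """Outcome of chromosome selection: retained records plus bookkeeping."""

    kept: list[ChromosomeSequence]
    dropped_ids: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_ids)

    def __iter__(self) -> Iterator[ChromosomeSequence]:
        return iter(self.kept)

    def __len__(self) -> int:
        return len(self.kept)


def filter_chromosomes(
    records: Iterable[ChromosomeSequence],
    min_length_mb: float = 1.0,
    name_excludes: Sequence[str] = DEFAULT_NAME_EXCLUDES,
    bases_per_mb: float = 1e6,
) -> FilterResult:
    """Select records that count as chromosomes / linkage groups.

    Retains records at least ``min_length_mb`` long whose name matches no
    exclude pattern (case-insensitive substring). Mirrors the manual curation
    applied to chromosome-level assembly records: mitochondria, unplaced
    scaffolds and random fragments are dropped. Idempotent, order-preserving.
    """
    if min_length_mb < 0:
        raise ValueError("min_length_mb must be >= 0")
    patterns = [re.compile(re.escape(p), re.IGNORECASE) for p in name_excludes]
    kept: list[ChromosomeSequence] = []
    dropped: list[str] = []
    for rec in records:
        excluded = any(p.search(rec.name) or p.search(rec.id) for p in patterns)
        if not excluded and rec.length_bp >= min_length_mb * bases_per_mb:
            kept.append(rec)
        else:
            dropped.append(rec.id)
    if dropped and not kept:
        warnings.warn(
            f"all {len(dropped)} records dropped by chromosome filter",
            stacklevel=2,
        )
    return FilterResult(kept=kept, dropped_ids=dropped)


_TABLE_REQUIRED = ("species", "chromosome", "length_mb", "gc_pct")


def read_chromosome_table(path: str | Path) -> list[ChromosomeTableRow]:
    """Read a per-chromosome TSV (species, chromosome, length_mb, gc_pct
    [, rep_pct]) into typed, validated rows.

    Raises a schema error for missing mandatory columns and a validation
    error citing the 1-based data row number for out-of-range values.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _TABLE_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    rows: list[ChromosomeTableRow] = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        rep = getattr(rec, "rep_pct", None)
        if rep is not None and pd.isna(rep):
            rep = None
        try:
            rows.append(
                ChromosomeTableRow(
                    species=str(rec.species),
                    chromosome=str(rec.chromosome),
                    length_mb=float(rec.length_mb),
                    gc_pct=float(rec.gc_pct),
                    rep_pct=None if rep is None else float(rep),
                )
            )
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: invalid row {i}: {err}") from err
    return rows


def c_value_to_mb(c_value_pg: float, mb_per_pg: float = MB_PER_PG) -> float:
    """Convert a haploid genome size in picograms (C-value) to megabases.

    The default factor is 978 Mb per picogram.
    """
    if c_value_pg <= 0:
        raise ValueError("C-value must be > 0 picograms")
    return c_value_pg * mb_per_pg
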