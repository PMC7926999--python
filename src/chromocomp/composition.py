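"""Window-wise and whole-chromosome GC% and repeat% of soft-masked sequence.

The central quantity is the composition of a genomic window split by repeat
status: GC% over assayed (unambiguous A/C/G/T) bases, the repeat fraction
rep% (lowercase soft-masked bases), and GC% computed separately inside the
repeat and non-repeat fractions. Windows tile the chromosome without overlap
so that window counts sum exactly to whole-chromosome counts; every percent
carries an explicit undefined state (``None``) when its denominator is zero
rather than a sentinel number.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genome_io import ChromosomeSequence

__all__ = [
    "BaseCounts",
    "WindowStat",
    "ChromosomeComposition",
    "GenomeComposition",
    "DEFAULT_WINDOW_BP",
    "window_partition",
    "base_counts",
    "window_composition",
    "chromosome_composition",
    "genome_composition",
    "apply_bed_mask",
    "read_bed",
    "windows_to_frame",
    "chromosomes_to_frame",
]

DEFAULT_WINDOW_BP = 100_000

# Byte-level classification tables. GC/AT cover upper and lower case;
# N and every IUPAC ambiguity code count as unknown (excluded from GC
# numerator and denominator alike). Anything else is invalid input.
_GC = b"GCgc"
_AT = b"ATat"
_UNKNOWN = b"NRYSWKMBDHVnryswkmbdhv"
_LOWER = b"acgtnryswkmbdhv"

_IS_GC = np.zeros(256, dtype=bool)
_IS_AT = np.zeros(256, dtype=bool)
_IS_UNKNOWN = np.zeros(256, dtype=bool)
_IS_LOWER = np.zeros(256, dtype=bool)
_IS_GC[list(_GC)] = True
_IS_AT[list(_AT)] = True
_IS_UNKNOWN[list(_UNKNOWN)] = True
_IS_LOWER[list(_LOWER)] = True
_IS_VALID = _IS_GC | _IS_AT | _IS_UNKNOWN


class BaseCounts(NamedTuple):
    """Base tallies of a sequence slice, split by repeat (lowercase) status."""

    gc: int
    at: int
    unknown: int
    rep_gc: int
    rep_at: int
    rep_span: int  # all lowercase bases, ambiguous included


def _as_bytes(residues: str) -> np.ndarray:
    try:
        raw = residues.encode("ascii")
    except UnicodeEncodeError as err:
        raise ValueError(f"non-ASCII residue at position {err.start}") from err
    return np.frombuffer(raw, dtype=np.uint8)


def _validate(b: np.ndarray) -> None:
    bad = ~_IS_VALID[b]
    if bad.any():
        pos = int(np.argmax(bad))
        raise ValueError(
            f"invalid residue {chr(b[pos])!r} at position {pos} "
            "(expected IUPAC nucleotide code)"
        )


def base_counts(residues: str) -> BaseCounts:
    """Classify every base of a slice, case-insensitively for GC/AT and
    with lowercase feeding the repeat tallies."""
    b = _as_bytes(residues)
    if b.size == 0:
        return BaseCounts(0, 0, 0, 0, 0, 0)
    _validate(b)
    gc = _IS_GC[b]
    at = _IS_AT[b]
    unk = _IS_UNKNOWN[b]
    low = _IS_LOWER[b]
    return BaseCounts(
        gc=int(gc.sum()),
        at=int(at.sum()),
        unknown=int(unk.sum()),
        rep_gc=int((gc & low).sum()),
        rep_at=int((at & low).sum()),
        rep_span=int(low.sum()),
    )


def window_partition(length_bp: int, window_bp: int) -> list[tuple[int, int]]:
    """Tile ``[0, length_bp)`` into consecutive half-open windows.

    The final window may be shorter; the tiles are non-overlapping and
    exhaustive, so window tallies sum exactly to whole-sequence tallies.
    """
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    starts = range(0, length_bp, window_bp)
    return [(s, min(s + window_bp, length_bp)) for s in starts]


def _pct(num: float, den: float) -> float | None:
    return 100.0 * num / den if den > 0 else None


@dataclass(frozen=True)
class WindowStat:
    """Composition of one genomic window, counts kept exact.

    Percent properties return ``None`` (undefined) when their denominator
    is zero — an all-N window has no GC%, a repeat-free window no repeat GC%.
    """

    chromosome: str
    start: int
    end: int
    gc_bp: int
    at_bp: int
    n_bp: int
    rep_gc_bp: int
    rep_at_bp: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")
        if self.rep_bp > self.effective_bp:
            raise ValueError("repeat bases exceed effective bases")

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    @property
    def effective_bp(self) -> int:
        """Unambiguous (assayed) bases in the window."""
        return self.gc_bp + self.at_bp

    @property
    def rep_bp(self) -> int:
        """Repeat-masked unambiguous bases."""
        return self.rep_gc_bp + self.rep_at_bp

    @property
    def gc_pct(self) -> float | None:
        return _pct(self.gc_bp, self.effective_bp)

    @property
    def rep_pct(self) -> float | None:
        return _pct(self.rep_bp, self.effective_bp)

    @property
    def gc_rep_pct(self) -> float | None:
        return _pct(self.rep_gc_bp, self.rep_bp)

    @property
    def gc_nonrep_pct(self) -> float | None:
        return _pct(self.gc_bp - self.rep_gc_bp, self.effective_bp - self.rep_bp)


def window_composition(
    chrom: ChromosomeSequence, window_bp: int = DEFAULT_WINDOW_BP
) -> list[WindowStat]:
    """Tally GC, AT, unknown and repeat counts per tiling window.

    Vectorised: the chromosome is classified once at the byte level and
    summed per window, so summing windows reproduces a single whole-sequence
    pass exactly.
    """
    b = _as_bytes(chrom.residues)
    _validate(b)
    tiles = window_partition(chrom.length_bp, window_bp)
    starts = np.fromiter((s for s, _ in tiles), dtype=np.int64, count=len(tiles))

    gc = _IS_GC[b]
    at = _IS_AT[b]
    unk = _IS_UNKNOWN[b]
    low = _IS_LOWER[b]

    def per_window(mask: np.ndarray) -> np.ndarray:
        return np.add.reduceat(mask, starts, dtype=np.int64)

    gc_w = per_window(gc)
    at_w = per_window(at)
    unk_w = per_window(unk)
    rep_gc_w = per_window(gc & low)
    rep_at_w = per_window(at & low)

    return [
        WindowStat(
            chromosome=chrom.id,
            start=s,
            end=e,
            gc_bp=int(gc_w[i]),
            at_bp=int(at_w[i]),
            n_bp=int(unk_w[i]),
            rep_gc_bp=int(rep_gc_w[i]),
            rep_at_bp=int(rep_at_w[i]),
        )
        for i, (s, e) in enumerate(tiles)
    ]


@dataclass(frozen=True)
class ChromosomeComposition:
    """Per-chromosome aggregate of window counts.

    ``gc_pct`` etc. pool the underlying counts (weighted by assayed bases),
    so they equal a single whole-chromosome pass regardless of window size.
    ``rep_pct_median_over_windows`` is the median of the defined window-level
    rep% values — the chromosome-level repeat statistic used when relating
    repeat load to chromosome size.
    """

    chromosome: str
    size_mb: float
    n_windows: int
    gc_bp: int
    at_bp: int
    n_bp: int
    rep_gc_bp: int
    rep_at_bp: int
    rep_pct_median_over_windows: float | None

    @property
    def effective_bp(self) -> int:
        return self.gc_bp + self.at_bp

    @property
    def rep_bp(self) -> int:
        return self.rep_gc_bp + self.rep_at_bp

    @property
    def gc_pct(self) -> float | None:
        return _pct(self.gc_bp, self.effective_bp)

    @property
    def rep_pct(self) -> float | None:
        return _pct(self.rep_bp, self.effective_bp)

    @property
    def gc_rep_pct(self) -> float | None:
        return _pct(self.rep_gc_bp, self.rep_bp)

    @property
    def gc_nonrep_pct(self) -> float | None:
        return _pct(self.gc_bp - self.rep_gc_bp, self.effective_bp - self.rep_bp)


def chromosome_composition(
    windows: Sequence[WindowStat],
    size_bp: int | None = None,
    bases_per_mb: float = 1e6,
) -> ChromosomeComposition:
    """Aggregate window statistics into one per-chromosome record.

    ``size_bp`` defaults to the end of the last window. ``bases_per_mb``
    sets the coordinate scale for ``size_mb`` (1e6 for real assemblies).
    """
    if not windows:
        raise ValueError("cannot aggregate an empty window list")
    chrom_ids = {w.chromosome for w in windows}
    if len(chrom_ids) != 1:
        raise ValueError(f"windows span multiple chromosomes: {sorted(chrom_ids)}")
    if size_bp is None:
        size_bp = max(w.end for w in windows)
    rep_pcts = [w.rep_pct for w in windows if w.rep_pct is not None]
    return ChromosomeComposition(
        chromosome=windows[0].chromosome,
        size_mb=size_bp / bases_per_mb,
        n_windows=len(windows),
        gc_bp=sum(w.gc_bp for w in windows),
        at_bp=sum(w.at_bp for w in windows),
        n_bp=sum(w.n_bp for w in windows),
        rep_gc_bp=sum(w.rep_gc_bp for w in windows),
        rep_at_bp=sum(w.rep_at_bp for w in windows),
        rep_pct_median_over_windows=(
            float(np.median(rep_pcts)) if rep_pcts else None
        ),
    )


@dataclass(frozen=True)
class GenomeComposition:
    """Whole-genome composition pooled from chromosome-level counts.

    Genome GC% and rep% are count-pooled, never unweighted means of
    per-chromosome percentages.
    """

    species: str
    chromosomes: tuple[ChromosomeComposition, ...]

    @property
    def assembly_size_mb(self) -> float:
        return sum(c.size_mb for c in self.chromosomes)

    @property
    def gc_pct(self) -> float | None:
        return _pct(
            sum(c.gc_bp for c in self.chromosomes),
            sum(c.effective_bp for c in self.chromosomes),
        )

    @property
    def rep_pct(self) -> float | None:
        return _pct(
            sum(c.rep_bp for c in self.chromosomes),
            sum(c.effective_bp for c in self.chromosomes),
        )


def genome_composition(
    per_chromosome: Iterable[ChromosomeComposition], species: str = ""
) -> GenomeComposition:
    chroms = tuple(per_chromosome)
    if not chroms:
        raise ValueError("cannot build a genome from zero chromosomes")
    return GenomeComposition(species=species, chromosomes=chroms)


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read a BED3+ file of repeat intervals (0-based, half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return list(df.itertuples(index=False, name=None))


def apply_bed_mask(
    chrom: ChromosomeSequence, intervals: Iterable[tuple[int, int]]
) -> ChromosomeSequence:
    """Lowercase the bases inside the given 0-based half-open intervals.

    Alternative repeat annotation route for assemblies distributed without
    soft-masking; out-of-bounds intervals are rejected.
    """
    b = bytearray(chrom.residues, "ascii")
    n = len(b)
    for start, end in intervals:
        if not 0 <= start < end <= n:
            raise ValueError(
                f"interval ({start}, {end}) outside [0, {n}) on {chrom.id}"
            )
        b[start:end] = bytes(b[start:end]).lower()
    return ChromosomeSequence(
        id=chrom.id,
        residues=b.decode("ascii"),
        name=chrom.name,
        species=chrom.species,
    )


def _round(x: float | None, nd: int = 6) -> float | None:
    return None if x is None else round(x, nd)


def windows_to_frame(windows: Sequence[WindowStat]) -> pd.DataFrame:
    """Per-window table (schema v1): one row per tile with composition
    percents; undefined percents are empty cells, never zeros."""
    return pd.DataFrame(
        {
            "chromosome": [w.chromosome for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "gc_pct": [_round(w.gc_pct) for w in windows],
            "rep_pct": [_round(w.rep_pct) for w in windows],
            "gc_rep_pct": [_round(w.gc_rep_pct) for w in windows],
            "gc_nonrep_pct": [_round(w.gc_nonrep_pct) for w in windows],
            "n_bp": [w.n_bp for w in windows],
        }
    )


def chromosomes_to_frame(
    comps: Sequence[ChromosomeComposition], species: str = ""
) -> pd.DataFrame:
    """Per-chromosome table (schema v1) mirroring ChromosomeComposition."""
    df = pd.DataFrame(
        {
            "chromosome": [c.chromosome for c in comps],
            "size_mb": [round(c.size_mb, 6) for c in comps],
            "gc_pct": [_round(c.gc_pct) for c in comps],
            "rep_pct": [_round(c.rep_pct) for c in comps],
            "rep_pct_median_over_windows": [
                _round(c.rep_pct_median_over_windows) for c in comps
            ],
            "gc_rep_pct": [_round(c.gc_rep_pct) for c in comps],
            "gc_nonrep_pct": [_round(c.gc_nonrep_pct) for c in comps],
            "n_windows": [c.n_windows for c in comps],
        }
    )
    if species:
        df.insert(0, "species", species)
    return df
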