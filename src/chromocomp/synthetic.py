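"""Synthetic soft-masked genomes with known compositional ground truth.

Stands in for downloaded chromosome-level assemblies: every downstream
stage (window composition, size–GC association, breakpoint estimation,
heterogeneity scoring, panel grouping) can be exercised against parameters
the generator controls exactly.

The model of a chromosome is deliberately simple and fully analysable:

* a per-chromosome target GC% set by a size model (constant, linear,
  hyperbolic or segmented in chromosome size) plus chromosome-level scatter;
* isochore-like segments whose lengths are exponential and whose GC is
  drawn around the chromosome target, giving controllable along-chromosome
  AT/GC heterogeneity;
* repeat tracts placed as a Poisson process of geometric-length runs,
  soft-masked (lowercased) and GC-shifted by a configurable offset, with
  the placement intensity corrected so the expected masked fraction equals
  the requested density despite tract overlap;
* assembly gaps as runs of N.

Bases are i.i.d. within a segment, so binomial error bounds apply to every
realized GC value. A fixed seed yields a byte-identical FASTA.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome_io import ChromosomeSequence, write_fasta

__all__ = [
    "GCModel",
    "SyntheticGenomeSpec",
    "GroundTruth",
    "simulate_chromosomes",
    "simulate_genome",
    "simulate_panel",
    "sample_points",
    "preset_points",
    "make_panel_spec",
    "default_panel_specs",
    "PANEL_PRESETS",
    "HETEROGENEITY_PRESETS",
]

_G, _C, _A, _T, _N = (ord(c) for c in "GCATN")


@dataclass(frozen=True)
class GCModel:
    """Target GC% as a function of chromosome size L (Mb).

    kinds: ``constant`` (a); ``linear`` (a + b·L); ``hyperbolic`` (a + b/L);
    ``segmented`` (GC = a at the breakpoint, slope b below it and
    ``slope_above`` beyond it, continuous).
    """

    kind: str
    a: float
    b: float = 0.0
    breakpoint_mb: float | None = None
    slope_above: float = 0.0

    def gc_at(self, sizes_mb: Sequence[float] | float) -> np.ndarray:
        L = np.asarray(sizes_mb, dtype=float)
        if self.kind == "constant":
            return np.full_like(L, self.a)
        if self.kind == "linear":
            return self.a + self.b * L
        if self.kind == "hyperbolic":
            return self.a + self.b / L
        if self.kind == "segmented":
            if self.breakpoint_mb is None:
                raise ValueError("segmented model needs breakpoint_mb")
            d = L - self.breakpoint_mb
            return np.where(
                L < self.breakpoint_mb,
                self.a + self.b * d,
                self.a + self.slope_above * d,
            )
        raise ValueError(f"unknown GC model kind {self.kind!r}")


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Full recipe for one simulated soft-masked genome.

    ``bases_per_mb`` sets the coordinate scale: nominal chromosome sizes in
    Mb can be emitted at reduced sequence length (see docs) while keeping
    the size axis; 1e6 gives real-scale sequence. Isochore segment lengths
    and window sizes are expressed on the same scale.
    """

    species: str
    chromosome_sizes_mb: tuple[float, ...]
    gc_model: GCModel
    gc_sigma: float = 0.5
    repeat_density: float = 0.3
    repeat_size_coupling: float = 0.0  # density change per Mb around the mean size
    repeat_gc_offset: float = 0.0  # percentage points added to GC inside repeats
    repeat_mean_len_bp: int = 500
    isochore_mean_mb: float = 0.3
    isochore_gc_sd: float = 1.0
    isochore_gc_values: tuple[float, ...] | None = None
    n_gap_rate_per_mb: float = 0.5
    n_gap_mean_bp: int = 300
    bases_per_mb: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosome_sizes_mb:
            raise ValueError("spec needs at least one chromosome")
        sizes = np.asarray(self.chromosome_sizes_mb, dtype=float)
        if np.any(sizes <= 0):
            raise ValueError("chromosome sizes must be positive")
        if not 0.0 <= self.repeat_density <= 0.99:
            raise ValueError("repeat_density must lie in [0, 0.99]")
        dens = self._densities(sizes)
        if np.any((dens < 0) | (dens > 0.99)):
            raise ValueError("repeat densities must lie in [0, 0.99]")
        gc = self.gc_model.gc_at(sizes)
        if np.any((gc <= 0) | (gc >= 100)):
            raise ValueError("model GC must lie strictly inside (0, 100)")
        if np.any((gc + self.repeat_gc_offset <= 0) | (gc + self.repeat_gc_offset >= 100)):
            raise ValueError("repeat GC (model GC + offset) escapes (0, 100)")

    def _densities(self, sizes: np.ndarray) -> np.ndarray:
        return np.clip(
            self.repeat_density
            + self.repeat_size_coupling * (sizes - sizes.mean()),
            0.0,
            0.99,
        )


@dataclass(frozen=True)
class GroundTruth:
    """Realized per-chromosome composition of an emitted genome.

    Every value in ``table`` is recomputable from the FASTA: the generator
    recounts the final byte array (after masking and gap insertion), so the
    truth is exact, not the pre-noise target.
    """

    species: str
    seed: int
    spec: SyntheticGenomeSpec
    table: pd.DataFrame  # chromosome, size_mb, length_bp, target_gc_pct, ...


def _segment_gc_per_base(
    rng: np.random.Generator,
    length_bp: int,
    mean_seg_bp: float,
    gc_center: float,
    gc_sd: float,
    gc_values: tuple[float, ...] | None,
) -> np.ndarray:
    if gc_values:
        seg = max(1, int(round(mean_seg_bp)))
        n_seg = math.ceil(length_bp / seg)
        gcs = np.array(
            [gc_values[i % len(gc_values)] for i in range(n_seg)], dtype=float
        )
        return np.repeat(gcs, seg)[:length_bp]
    if gc_sd <= 0:
        return np.full(length_bp, gc_center)
    if mean_seg_bp >= length_bp:
        gc = float(np.clip(rng.normal(gc_center, gc_sd), 1.0, 99.0))
        return np.full(length_bp, gc)
    # exponential segment lengths until the chromosome is covered
    est = int(length_bp / mean_seg_bp * 1.5) + 8
    lens: list[int] = []
    total = 0
    while total < length_bp:
        draw = rng.exponential(mean_seg_bp, size=est)
        for d in draw:
            l = max(1, int(d))
            lens.append(l)
            total += l
            if total >= length_bp:
                break
    gcs = rng.normal(gc_center, gc_sd, size=len(lens))
    gcs = np.clip(gcs, 1.0, 99.0)
    return np.repeat(gcs, lens)[:length_bp]


def _repeat_mask(
    rng: np.random.Generator,
    length_bp: int,
    density: float,
    mean_len_bp: int,
) -> np.ndarray:
    if density <= 0:
        return np.zeros(length_bp, dtype=bool)
    # Poisson boolean model: coverage of uniformly placed tracts is
    # 1 - exp(-intensity), so invert to hit the requested masked fraction.
    intensity = -math.log1p(-density)
    n_tracts = rng.poisson(intensity * length_bp / mean_len_bp)
    if n_tracts == 0:
        return np.zeros(length_bp, dtype=bool)
    starts = rng.integers(0, length_bp, size=n_tracts)
    lens = rng.geometric(1.0 / mean_len_bp, size=n_tracts)
    ends = np.minimum(starts + lens, length_bp)
    delta = np.zeros(length_bp + 1, dtype=np.int32)
    np.add.at(delta, starts, 1)
    np.add.at(delta, ends, -1)
    return np.cumsum(delta[:-1]) > 0


def _draw_bases(rng: np.random.Generator, gc_prob: np.ndarray) -> np.ndarray:
    u = rng.random(gc_prob.size)
    half_gc = gc_prob / 2.0
    mid = gc_prob + (1.0 - gc_prob) / 2.0
    return np.where(
        u < half_gc, _G, np.where(u < gc_prob, _C, np.where(u < mid, _A, _T))
    ).astype(np.uint8)


def _insert_gaps(
    rng: np.random.Generator,
    arr: np.ndarray,
    size_mb: float,
    rate_per_mb: float,
    mean_gap_bp: int,
) -> None:
    if rate_per_mb <= 0:
        return
    n_gaps = rng.poisson(rate_per_mb * size_mb)
    if n_gaps == 0:
        return
    starts = rng.integers(0, arr.size, size=n_gaps)
    lens = rng.geometric(1.0 / mean_gap_bp, size=n_gaps)
    for s, l in zip(starts, lens):
        arr[s : min(s + l, arr.size)] = _N


def _recount(arr: np.ndarray) -> dict[str, float | None]:
    upper = arr - 32 * ((arr >= 97) & (arr <= 122)).astype(np.uint8)
    lower_mask = (arr >= 97) & (arr <= 122)
    gc = (upper == _G) | (upper == _C)
    at = (upper == _A) | (upper == _T)
    eff = int(gc.sum() + at.sum())
    rep = int((gc & lower_mask).sum() + (at & lower_mask).sum())
    rep_gc = int((gc & lower_mask).sum())
    return {
        "realized_gc_pct": 100.0 * gc.sum() / eff if eff else None,
        "realized_rep_pct": 100.0 * rep / eff if eff else None,
        "realized_gc_rep_pct": 100.0 * rep_gc / rep if rep else None,
        "n_bp": int(arr.size - eff),
    }


def simulate_chromosomes(
    spec: SyntheticGenomeSpec,
) -> tuple[list[ChromosomeSequence], GroundTruth]:
    """Generate the chromosomes of one genome, in memory, with ground truth."""
    rng = np.random.default_rng(spec.seed)
    sizes = np.asarray(spec.chromosome_sizes_mb, dtype=float)
    model_gc = spec.gc_model.gc_at(sizes)
    targets = model_gc + (
        rng.normal(0.0, spec.gc_sigma, size=sizes.size)
        if spec.gc_sigma > 0
        else 0.0
    )
    targets = np.clip(targets, 1.0, 99.0)
    densities = spec._densities(sizes)

    records: list[ChromosomeSequence] = []
    rows: list[dict] = []
    mean_seg_bp = spec.isochore_mean_mb * spec.bases_per_mb
    for i, (size_mb, gc_t, dens) in enumerate(zip(sizes, targets, densities)):
        length_bp = max(1, int(round(size_mb * spec.bases_per_mb)))
        gc_base = _segment_gc_per_base(
            rng,
            length_bp,
            mean_seg_bp,
            float(gc_t),
            spec.isochore_gc_sd,
            spec.isochore_gc_values,
        )
        mask = _repeat_mask(rng, length_bp, float(dens), spec.repeat_mean_len_bp)
        gc_prob = np.clip(
            gc_base + spec.repeat_gc_offset * mask, 0.5, 99.5
        ) / 100.0
        arr = _draw_bases(rng, gc_prob)
        arr[mask] += 32  # lowercase = soft-masked
        _insert_gaps(
            rng, arr, float(size_mb), spec.n_gap_rate_per_mb, spec.n_gap_mean_bp
        )
        cid = f"chr{i + 1}"
        records.append(
            ChromosomeSequence(
                id=cid,
                residues=arr.tobytes().decode("ascii"),
                name=cid,
                species=spec.species,
            )
        )
        row = {
            "species": spec.species,
            "chromosome": cid,
            "size_mb": float(size_mb),
            "length_bp": length_bp,
            "target_gc_pct": float(gc_t),
            "target_rep_density": float(dens),
        }
        row.update(_recount(arr))
        rows.append(row)

    truth = GroundTruth(
        species=spec.species,
        seed=spec.seed,
        spec=spec,
        table=pd.DataFrame(rows),
    )
    return records, truth


def simulate_genome(
    spec: SyntheticGenomeSpec, out_dir: str | Path
) -> tuple[Path, GroundTruth]:
    """Emit one genome as soft-masked FASTA plus its ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, truth = simulate_chromosomes(spec)
    path = write_fasta(records, out_dir / f"{spec.species}.fa")
    return path, truth


def _spec_echo(spec: SyntheticGenomeSpec) -> dict:
    d = asdict(spec)
    d["gc_model"] = asdict(spec.gc_model)
    return d


def simulate_panel(
    specs: Sequence[SyntheticGenomeSpec], out_dir: str | Path
) -> tuple[list[Path], pd.DataFrame, Path]:
    """Emit a multi-species panel: FASTAs, pooled truth TSV and a manifest.

    Returns (fasta paths, truth table, manifest path). The manifest echoes
    every spec with its seed and coordinate scale, so a run is fully
    reproducible from the manifest alone.
    """
    if not specs:
        raise ValueError("panel needs at least one genome spec")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    tables: list[pd.DataFrame] = []
    for spec in specs:
        path, truth = simulate_genome(spec, out_dir)
        paths.append(path)
        tables.append(truth.table)
    truth_df = pd.concat(tables, ignore_index=True)
    truth_df.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    manifest = {
        "n_species": len(specs),
        "species": [s.species for s in specs],
        "specs": [_spec_echo(s) for s in specs],
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths, truth_df, manifest_path


# ---------------------------------------------------------------------------
# Presets mirroring the qualitative size-GC patterns seen across chordate
# lineages: lancelet-like positive, platyfish-like negative, zebrafish-like
# flat, avian-like hyperbolic, and micro/macro panels with breakpoints at
# 50 Mb and 20 Mb.
# ---------------------------------------------------------------------------

def _seg_sizes(bp_mb: float, lo: float, hi: float, n_micro: int, n_macro: int):
    return tuple(
        np.round(
            np.concatenate(
                [
                    np.geomspace(lo, bp_mb * 0.96, n_micro),
                    np.linspace(bp_mb * 1.08, hi, n_macro),
                ]
            ),
            3,
        )
    )


PANEL_PRESETS: dict[str, dict] = {
    "positive": dict(
        sizes=tuple(np.round(np.linspace(17.1, 35.3, 19), 3)),
        model=GCModel("linear", a=36.0, b=0.15),
        sigma=0.5,
        density=0.25,
        offset=-2.0,
        iso_sd=1.0,
        lineage="cephalochordate",
    ),
    "negative": dict(
        sizes=tuple(np.round(np.linspace(20.0, 35.0, 24), 3)),
        model=GCModel("linear", a=45.0, b=-0.2),
        sigma=0.5,
        density=0.3,
        offset=-2.0,
        iso_sd=1.0,
        lineage="teleost",
    ),
    "none": dict(
        sizes=tuple(np.round(np.linspace(37.5, 59.6, 25), 3)),
        model=GCModel("constant", a=36.5),
        sigma=0.5,
        density=0.45,
        offset=-3.0,
        iso_sd=1.0,
        lineage="teleost",
    ),
    "hyperbolic": dict(
        sizes=tuple(np.round(np.geomspace(5.0, 200.0, 30), 3)),
        model=GCModel("hyperbolic", a=41.0, b=120.0),
        sigma=0.4,
        density=0.2,
        offset=0.0,
        iso_sd=4.0,
        lineage="bird",
    ),
    "segmented-50Mb": dict(
        sizes=_seg_sizes(50.0, 5.0, 200.0, 18, 12),
        model=GCModel("segmented", a=40.0, b=-0.8, breakpoint_mb=50.0),
        sigma=0.3,
        density=0.2,
        offset=0.0,
        iso_sd=4.0,
        lineage="reptile",
    ),
    "segmented-20Mb": dict(
        sizes=_seg_sizes(20.0, 5.0, 100.0, 15, 15),
        model=GCModel("segmented", a=40.0, b=-0.8, breakpoint_mb=20.0),
        sigma=0.3,
        density=0.25,
        offset=0.0,
        iso_sd=2.0,
        lineage="non-teleost fish",
    ),
}

#: Alias: a flat panel is the "none" pattern.
PANEL_PRESETS["flat"] = PANEL_PRESETS["none"]

#: Along-chromosome heterogeneity contrast: same overall GC, different
#: isochore GC spread (fish-homogeneous vs mammal/gar-heterogeneous).
HETEROGENEITY_PRESETS: dict[str, dict] = {
    "homogeneous": dict(
        sizes=(1.5,), model=GCModel("constant", a=40.0), sigma=0.0,
        density=0.3, offset=0.0, iso_sd=0.8, iso_mean_mb=0.3,
    ),
    "heterogeneous": dict(
        sizes=(1.5,), model=GCModel("constant", a=42.0), sigma=0.0,
        density=0.3, offset=0.0, iso_sd=8.0, iso_mean_mb=0.3,
    ),
}


def make_panel_spec(
    preset: str,
    seed: int,
    species: str | None = None,
    bases_per_mb: float = 1e6,
) -> SyntheticGenomeSpec:
    """Instantiate a named preset as a concrete genome spec."""
    table = {**PANEL_PRESETS, **HETEROGENEITY_PRESETS}
    if preset not in table:
        raise KeyError(
            f"unknown preset {preset!r}; available: {sorted(table)}"
        )
    p = table[preset]
    return SyntheticGenomeSpec(
        species=species or preset.replace("-", "_"),
        chromosome_sizes_mb=p["sizes"],
        gc_model=p["model"],
        gc_sigma=p["sigma"],
        repeat_density=p["density"],
        repeat_gc_offset=p["offset"],
        isochore_gc_sd=p["iso_sd"],
        isochore_mean_mb=p.get("iso_mean_mb", 0.3),
        bases_per_mb=bases_per_mb,
        seed=seed,
    )


DEFAULT_PANEL = (
    "positive",
    "negative",
    "none",
    "hyperbolic",
    "segmented-50Mb",
    "segmented-20Mb",
)


def default_panel_specs(
    seed: int, bases_per_mb: float = 1e6
) -> list[SyntheticGenomeSpec]:
    """One spec per default preset, with per-species seeds derived from
    ``seed`` (kept below 2^31)."""
    return [
        make_panel_spec(
            name, seed=(seed * 1009 + i) % (2**31), bases_per_mb=bases_per_mb
        )
        for i, name in enumerate(DEFAULT_PANEL)
    ]


def sample_points(
    model: GCModel,
    sizes_mb: Sequence[float],
    sigma: float,
    rng: np.random.Generator | int,
) -> list[tuple[float, float]]:
    """Tabular shortcut: draw per-chromosome (size, GC) points from a size
    model with Gaussian chromosome-level scatter — the panel-level view of
    the generator, without emitting sequence."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sizes = np.asarray(sizes_mb, dtype=float)
    gc = model.gc_at(sizes) + rng.normal(0.0, sigma, size=sizes.size)
    return list(zip(sizes.tolist(), gc.tolist()))


def preset_points(
    preset: str, rng: np.random.Generator | int
) -> tuple[list[tuple[float, float]], GCModel]:
    """(size, GC) points for a named preset plus the true model."""
    p = PANEL_PRESETS[preset]
    return sample_points(p["model"], p["sizes"], p["sigma"], rng), p["model"]
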