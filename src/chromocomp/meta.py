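"""Cross-species panel assembly, heterogeneity scoring and size/GC grouping.

Summaries never re-average percentages: pooled statistics are carried as
counts from the composition layer, so panel values equal a recomputation
from the raw windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering

from . import association
from .composition import DEFAULT_WINDOW_BP, GenomeComposition, WindowStat
from .genome_io import AssemblyMetadata, LINEAGE_GROUPS

__all__ = [
    "SpeciesSummary",
    "HeterogeneityScore",
    "build_panel",
    "heterogeneity_score",
    "group_by_size_gc",
    "distribution_summary",
    "DistributionSummary",
]


@dataclass(frozen=True)
class SpeciesSummary:
    """One panel row: a species' assembly-level compositional profile."""

    species: str
    lineage_group: str
    assembly_size_mb: float
    gc_pct: float | None
    rep_pct: float | None
    n_chromosomes: int
    min_chromosome_mb: float
    max_chromosome_mb: float
    association_label: str
    heterogeneity_gc_sd: float | None = None


@dataclass(frozen=True)
class HeterogeneityScore:
    """Along-genome AT/GC heterogeneity: SD of window GC% at a fixed
    window size. Homogeneous (typical teleost) genomes score low; isochore-
    structured (mammal/bird/gar-like) genomes score high."""

    gc_sd: float
    window_bp: int
    n_windows: int


def heterogeneity_score(
    windows: Iterable[WindowStat],
    window_bp: int = DEFAULT_WINDOW_BP,
    min_effective_frac: float = 0.2,
) -> HeterogeneityScore:
    """Standard deviation of defined window GC% over a genome.

    Gap-dominated windows (assayed bases below ``min_effective_frac`` of
    the span) are excluded. Invariant under chromosome relabeling and
    window order.
    """
    gcs = [
        w.gc_pct
        for w in windows
        if w.gc_pct is not None
        and w.effective_bp >= min_effective_frac * w.span_bp
    ]
    if not gcs:
        raise ValueError("no defined windows to score")
    arr = np.asarray(gcs, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return HeterogeneityScore(gc_sd=sd, window_bp=window_bp, n_windows=arr.size)


def _label_for(genome: GenomeComposition) -> str:
    pts = [
        (c.size_mb, c.gc_pct)
        for c in genome.chromosomes
        if c.gc_pct is not None
    ]
    if len(pts) < 3:
        return "n/a"
    try:
        return association.fit_all(pts).label
    except (association.SingularFitError, ValueError):
        return "n/a"


def build_panel(
    genomes: Iterable[GenomeComposition],
    metadata: Mapping[str, AssemblyMetadata] | None = None,
    heterogeneity: Mapping[str, HeterogeneityScore] | None = None,
) -> list[SpeciesSummary]:
    """One summary row per species, ordered by lineage then species name.

    Genome GC%/rep% are the count-pooled values from the composition layer;
    the association label is derived from the per-chromosome (size, GC%)
    points via AIC model comparison when at least three chromosomes exist.
    """
    metadata = metadata or {}
    heterogeneity = heterogeneity or {}
    rows: list[SpeciesSummary] = []
    for g in genomes:
        meta = metadata.get(g.species)
        sizes = [c.size_mb for c in g.chromosomes]
        het = heterogeneity.get(g.species)
        rows.append(
            SpeciesSummary(
                species=g.species,
                lineage_group=meta.lineage_group if meta else "teleost",
                assembly_size_mb=g.assembly_size_mb,
                gc_pct=g.gc_pct,
                rep_pct=g.rep_pct,
                n_chromosomes=len(g.chromosomes),
                min_chromosome_mb=min(sizes),
                max_chromosome_mb=max(sizes),
                association_label=_label_for(g),
                heterogeneity_gc_sd=het.gc_sd if het else None,
            )
        )
    lineage_rank = {name: i for i, name in enumerate(LINEAGE_GROUPS)}
    rows.sort(key=lambda r: (lineage_rank.get(r.lineage_group, 99), r.species))
    return rows


def panel_to_frame(panel: Sequence[SpeciesSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in panel])


def group_by_size_gc(
    panel: Sequence[SpeciesSummary] | pd.DataFrame,
    k: int,
) -> pd.DataFrame:
    """Partition species into ``k`` groups by genome size and GC%.

    Agglomerative (Ward) clustering on standardized (log10 assembly size,
    genome GC%). Group labels are renumbered by ascending mean genome size,
    which makes the partition deterministic and input-order invariant.
    """
    if isinstance(panel, pd.DataFrame):
        df = panel.copy()
    else:
        df = panel_to_frame(panel)
    n = len(df)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} species in the panel")
    X = np.column_stack(
        [
            np.log10(df["assembly_size_mb"].to_numpy(dtype=float)),
            df["gc_pct"].to_numpy(dtype=float),
        ]
    )
    Z = stats.zscore(X, axis=0, ddof=0)
    Z = np.nan_to_num(Z)  # a constant column carries no information
    if k == 1:
        raw = np.zeros(n, dtype=int)
    else:
        raw = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(Z)
    order = (
        pd.Series(np.log10(df["assembly_size_mb"].to_numpy(dtype=float)))
        .groupby(raw)
        .mean()
        .sort_values()
        .index
    )
    relabel = {old: new for new, old in enumerate(order)}
    df = df.assign(group=[relabel[g] for g in raw])
    return df.sort_values(["group", "species"], kind="stable").reset_index(
        drop=True
    )


@dataclass(frozen=True)
class DistributionSummary:
    """Order statistics plus a density grid (violin-plot backing data)."""

    n: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    density_x: tuple[float, ...]
    density_y: tuple[float, ...]


def distribution_summary(
    values: Iterable[float], n_grid: int = 128
) -> DistributionSummary:
    """Exact quantiles of the values; the KDE grid is for plotting only."""
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size == 0:
        raise ValueError("no values to summarise")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    lo, hi = float(arr.min()), float(arr.max())
    if arr.size > 1 and hi > lo:
        kde = stats.gaussian_kde(arr)
        grid = np.linspace(lo, hi, n_grid)
        dens = kde(grid)
    else:
        grid = np.array([lo])
        dens = np.array([1.0])
    return DistributionSummary(
        n=int(arr.size),
        minimum=lo,
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        maximum=hi,
        density_x=tuple(float(g) for g in grid),
        density_y=tuple(float(d) for d in dens),
    )
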