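"""Models of per-chromosome GC% (or rep%) against chromosome size.

Four model families describe the size–composition relationships observed
across chordate assemblies:

* ``null`` — intercept only (no association),
* ``linear`` — GC = b0 + b1·L (the common teleost/mammal pattern),
* ``hyperbolic`` — GC = a + b/L, linear in 1/L; with b > 0 it captures the
  GC enrichment of microchromosomes that levels off in macrochromosomes
  (the avian/reptilian/ancient-fish curve),
* ``segmented`` — a continuous two-slope piecewise-linear fit whose
  breakpoint locates the chromosome size where GC% stops depending on size
  (around 50 Mb in birds, reptiles and chondrichthyans; around 20 Mb in
  sterlet and gar).

All families are linear in their parameters given the breakpoint, so the
segmented fit is an exhaustive grid search over candidate breakpoints
minimising residual sum of squares. Models are compared by AIC computed on
a common convention, AIC = n·ln(RSS/n) + 2k, with the breakpoint counted
as a parameter (k = 1, 2, 2, 4 respectively).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .composition import ChromosomeComposition, WindowStat

__all__ = [
    "SingularFitError",
    "AssociationFit",
    "ModelComparison",
    "SizeClass",
    "DEFAULT_MICRO_THRESHOLD_MB",
    "fit_null",
    "fit_linear",
    "fit_hyperbolic",
    "estimate_breakpoint",
    "fit_all",
    "compare_models",
    "classify_size",
    "rep_vs_size",
    "window_gc_vs_rep",
    "GcRepFit",
    "adjust_pvalues",
]

DEFAULT_MICRO_THRESHOLD_MB = 30.0

#: Evidence margin on AIC differences: a model "clearly beats" another only
#: when its AIC is lower by more than this (conventional ΔAIC > 2 rule).
AIC_EVIDENCE_MARGIN = 2.0

_KIND_ORDER = {"null": 0, "linear": 1, "hyperbolic": 2, "segmented": 3}


class SingularFitError(ValueError):
    """Degenerate design (e.g. all chromosome sizes equal)."""


def _xy(points: Iterable[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (size, response) pairs")
    return arr[:, 0], arr[:, 1]


def _aic(n: int, rss: float, k: int) -> float:
    return n * float(np.log(max(rss, 1e-300) / n)) + 2 * k


def _r_squared(y: np.ndarray, rss: float) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0.0:
        return 0.0
    return max(0.0, min(1.0, 1.0 - rss / tss))


@dataclass(frozen=True)
class AssociationFit:
    """A fitted size–response model with its diagnostics.

    ``params`` holds the family's named coefficients; ``conf_int`` the 95%
    intervals where the underlying OLS provides them.
    """

    kind: str
    params: Mapping[str, float]
    n_points: int
    rss: float
    r_squared: float
    aic: float
    f_test_p: float | None = None
    stderr: Mapping[str, float] = field(default_factory=dict)
    conf_int: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def predict(self, sizes: np.ndarray | float) -> np.ndarray:
        x = np.asarray(sizes, dtype=float)
        p = self.params
        if self.kind == "null":
            return np.full_like(x, p["mean"], dtype=float)
        if self.kind == "linear":
            return p["intercept"] + p["slope"] * x
        if self.kind == "hyperbolic":
            return p["a"] + p["b"] / x
        if self.kind == "segmented":
            hinge = np.maximum(0.0, x - p["breakpoint_mb"])
            return p["intercept"] + p["slope_below"] * x + (
                p["slope_above"] - p["slope_below"]
            ) * hinge
        raise ValueError(f"unknown model kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "params": dict(self.params),
            "n_points": self.n_points,
            "rss": self.rss,
            "r_squared": self.r_squared,
            "aic": self.aic,
            "f_test_p": self.f_test_p,
            "stderr": dict(self.stderr),
            "conf_int": {k: list(v) for k, v in self.conf_int.items()},
        }


def _check_points(x: np.ndarray, y: np.ndarray, min_n: int = 3) -> None:
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points, got {x.size}")
    if np.any(x <= 0):
        raise ValueError("chromosome sizes must be positive")


def fit_null(points: Iterable[tuple[float, float]]) -> AssociationFit:
    """Intercept-only reference model (no size dependence)."""
    x, y = _xy(points)
    _check_points(x, y)
    mean = float(y.mean())
    rss = float(np.sum((y - mean) ** 2))
    se = float(y.std(ddof=1) / np.sqrt(y.size)) if y.size > 1 else 0.0
    return AssociationFit(
        kind="null",
        params={"mean": mean},
        n_points=int(x.size),
        rss=rss,
        r_squared=0.0,
        aic=_aic(x.size, rss, k=1),
        f_test_p=None,
        stderr={"mean": se},
    )


def _ols_fit(
    x_design: np.ndarray,
    y: np.ndarray,
    kind: str,
    names: Sequence[str],
    k: int,
) -> AssociationFit:
    X = np.column_stack([np.ones(len(y)), x_design])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError(
            f"degenerate design for {kind} fit (constant predictor)"
        )
    res = sm.OLS(y, X).fit()
    rss = float(res.ssr)
    r2 = _r_squared(y, rss)
    fp = float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0
    ci = res.conf_int(alpha=0.05)
    ci = np.asarray(ci, dtype=float)
    params = {name: float(v) for name, v in zip(names, res.params)}
    return AssociationFit(
        kind=kind,
        params=params,
        n_points=int(y.size),
        rss=rss,
        r_squared=r2,
        aic=_aic(y.size, rss, k=k),
        f_test_p=fp,
        stderr={name: float(v) for name, v in zip(names, res.bse)},
        conf_int={
            name: (float(lo), float(hi))
            for name, (lo, hi) in zip(names, ci)
        },
    )


def fit_linear(points: Iterable[tuple[float, float]]) -> AssociationFit:
    """OLS of the response on chromosome size: response = intercept + slope·L."""
    x, y = _xy(points)
    _check_points(x, y)
    return _ols_fit(x, y, "linear", ("intercept", "slope"), k=2)


def fit_hyperbolic(points: Iterable[tuple[float, float]]) -> AssociationFit:
    """OLS of the response on inverse size: response = a + b/L.

    Linear in its parameters, hence deterministic; b > 0 encodes GC
    enrichment of small chromosomes.
    """
    x, y = _xy(points)
    _check_points(x, y)
    return _ols_fit(1.0 / x, y, "hyperbolic", ("a", "b"), k=2)


def _segmented_design(x: np.ndarray, bp: float) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - bp)])


def estimate_breakpoint(
    points: Iterable[tuple[float, float]],
    candidate_grid: Sequence[float] | None = None,
    min_per_side: int = 3,
) -> AssociationFit:
    """Continuous two-segment piecewise-linear fit with grid-searched
    breakpoint.

    Candidates default to the midpoints of adjacent observed sizes; each
    candidate must leave at least ``min_per_side`` points on both sides.
    The breakpoint minimising total RSS wins; ties break toward the smaller
    breakpoint.
    """
    x, y = _xy(points)
    _check_points(x, y, min_n=2 * min_per_side)
    if candidate_grid is None:
        xs = np.unique(x)
        candidate_grid = ((xs[:-1] + xs[1:]) / 2.0).tolist()
    feasible = [
        float(bp)
        for bp in sorted(candidate_grid)
        if (x < bp).sum() >= min_per_side and (x >= bp).sum() >= min_per_side
        and x.min() < bp < x.max()
    ]
    if not feasible:
        raise SingularFitError(
            "no feasible breakpoint candidate with enough points on both sides"
        )
    best_bp, best_rss = None, np.inf
    for bp in feasible:  # ascending, strict '<' keeps the smaller tie-winner
        X = _segmented_design(x, bp)
        _, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < 3:
            continue
        rss = float(res[0]) if res.size else float(
            np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        )
        if rss < best_rss:
            best_bp, best_rss = bp, rss
    if best_bp is None:
        raise SingularFitError("segmented design degenerate at every candidate")

    X = _segmented_design(x, best_bp)
    res = sm.OLS(y, X).fit()
    beta = np.asarray(res.params, dtype=float)
    rss = float(res.ssr)
    n = int(y.size)
    k = 4  # intercept, two slopes, breakpoint
    r2 = _r_squared(y, rss)
    tss = float(np.sum((y - y.mean()) ** 2))
    if rss > 0 and n > k:
        f_stat = ((tss - rss) / 3.0) / (rss / (n - k))
        f_p = float(stats.f.sf(f_stat, 3, n - k))
    else:
        f_p = 0.0 if tss > rss else 1.0
    names = ("intercept", "slope_below", "slope_delta")
    return AssociationFit(
        kind="segmented",
        params={
            "intercept": float(beta[0]),
            "slope_below": float(beta[1]),
            "slope_above": float(beta[1] + beta[2]),
            "breakpoint_mb": float(best_bp),
        },
        n_points=n,
        rss=rss,
        r_squared=r2,
        aic=_aic(n, rss, k=k),
        f_test_p=f_p,
        stderr={name: float(v) for name, v in zip(names, res.bse)},
    )


@dataclass(frozen=True)
class ModelComparison:
    """AIC ranking of candidate fits plus the qualitative association label."""

    ranked: tuple[AssociationFit, ...]
    label: str  # positive | negative | none

    @property
    def best(self) -> AssociationFit:
        return self.ranked[0]

    def delta_aic(self, kind_a: str, kind_b: str) -> float:
        by_kind = {f.kind: f for f in self.ranked}
        return by_kind[kind_a].aic - by_kind[kind_b].aic


def _association_sign(fit: AssociationFit) -> float:
    if fit.kind == "linear":
        return float(np.sign(fit.params["slope"]))
    if fit.kind == "hyperbolic":
        # GC = a + b/L decreases with size when b > 0
        return float(-np.sign(fit.params["b"]))
    if fit.kind == "segmented":
        return float(np.sign(fit.params["slope_below"]))
    return 0.0


def compare_models(
    fits: Iterable[AssociationFit],
    p_max: float = 0.05,
) -> ModelComparison:
    """Rank fits by AIC and derive the association label.

    The label is "none" when the best model is the null model or its
    overall F-test is non-significant; otherwise the sign of the best
    model's size dependence sets "positive" or "negative".
    """
    ranked = tuple(
        sorted(fits, key=lambda f: (f.aic, _KIND_ORDER.get(f.kind, 9)))
    )
    if not ranked:
        raise ValueError("no fits to compare")
    best = ranked[0]
    if best.kind == "null" or best.f_test_p is None or best.f_test_p >= p_max:
        label = "none"
    else:
        sign = _association_sign(best)
        label = "positive" if sign > 0 else "negative" if sign < 0 else "none"
    return ModelComparison(ranked=ranked, label=label)


def fit_all(
    points: Iterable[tuple[float, float]],
    include_segmented: bool = True,
    p_max: float = 0.05,
) -> ModelComparison:
    """Fit null, linear, hyperbolic (and segmented when feasible), compare."""
    pts = list(points)
    fits = [fit_null(pts), fit_linear(pts), fit_hyperbolic(pts)]
    if include_segmented:
        try:
            fits.append(estimate_breakpoint(pts))
        except (SingularFitError, ValueError):
            pass
    return compare_models(fits, p_max=p_max)


@dataclass(frozen=True)
class SizeClass:
    """Micro/macro call for one chromosome at a stated size threshold."""

    chromosome: str
    size_mb: float
    size_class: str  # micro | macro
    threshold_mb: float


def classify_size(
    sizes_mb: Sequence[float],
    threshold_mb: float = DEFAULT_MICRO_THRESHOLD_MB,
    ids: Sequence[str] | None = None,
) -> list[SizeClass]:
    """Call chromosomes micro (< threshold) or macro (>= threshold)."""
    if ids is None:
        ids = [f"chr{i + 1}" for i in range(len(sizes_mb))]
    return [
        SizeClass(
            chromosome=cid,
            size_mb=float(s),
            size_class="micro" if s < threshold_mb else "macro",
            threshold_mb=threshold_mb,
        )
        for cid, s in zip(ids, sizes_mb)
    ]


def rep_vs_size(
    compositions: Iterable[ChromosomeComposition],
) -> AssociationFit:
    """Linear fit of the per-chromosome median window rep% on chromosome size."""
    pts = [
        (c.size_mb, c.rep_pct_median_over_windows)
        for c in compositions
        if c.rep_pct_median_over_windows is not None
    ]
    return fit_linear(pts)


@dataclass(frozen=True)
class GcRepFit:
    """Per-chromosome window-level GC ~ rep regression plus the rep% median."""

    chromosome: str
    fit: AssociationFit | None
    singular: bool
    median_rep_pct: float | None
    n_windows_used: int


def window_gc_vs_rep(
    windows: Iterable[WindowStat],
    min_effective_frac: float = 0.2,
) -> dict[str, GcRepFit]:
    """Regress window GC% on window rep% within each chromosome.

    Windows with undefined GC% or rep%, or with fewer assayed bases than
    ``min_effective_frac`` of their span (gap-dominated windows), are
    excluded. Chromosomes whose windows all share one rep% value are
    flagged singular rather than fitted.
    """
    by_chrom: dict[str, list[WindowStat]] = {}
    for w in windows:
        by_chrom.setdefault(w.chromosome, []).append(w)
    out: dict[str, GcRepFit] = {}
    for chrom, ws in by_chrom.items():
        usable = [
            w
            for w in ws
            if w.gc_pct is not None
            and w.rep_pct is not None
            and w.effective_bp >= min_effective_frac * w.span_bp
        ]
        reps = np.array([w.rep_pct for w in usable], dtype=float)
        med = float(np.median(reps)) if reps.size else None
        fit = None
        singular = False
        if reps.size >= 3 and np.ptp(reps) > 0:
            gcs = np.array([w.gc_pct for w in usable], dtype=float)
            try:
                # rep% may legitimately be 0, so bypass the size-positivity check
                fit = _ols_fit(reps, gcs, "linear", ("intercept", "slope"), k=2)
            except SingularFitError:
                singular = True
        elif reps.size >= 3:
            singular = True
        out[chrom] = GcRepFit(
            chromosome=chrom,
            fit=fit,
            singular=singular,
            median_rep_pct=med,
            n_windows_used=int(reps.size),
        )
    return out


def adjust_pvalues(pvalues: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Benjamini–Hochberg (default) adjustment for panel-wide screens."""
    return multipletests(np.asarray(pvalues, dtype=float), method=method)[1]
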