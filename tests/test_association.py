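import numpy as np
import pytest

from chromocomp.association import (
    SingularFitError,
    classify_size,
    compare_models,
    estimate_breakpoint,
    fit_all,
    fit_hyperbolic,
    fit_linear,
    fit_null,
    rep_vs_size,
    window_gc_vs_rep,
)
from chromocomp.composition import WindowStat, chromosome_composition
from chromocomp.synthetic import GCModel, sample_points


def _linear_points(slope=-0.1, intercept=45.0, n=10, lo=10.0, hi=60.0):
    x = np.linspace(lo, hi, n)
    return list(zip(x, intercept + slope * x))


class TestLinearFit:
    def test_collinear_points_recovered_exactly(self):
        fit = fit_linear(_linear_points())
        assert fit.params["slope"] == pytest.approx(-0.1)
        assert fit.params["intercept"] == pytest.approx(45.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_constant_response(self):
        fit = fit_linear([(x, 40.0) for x in (10, 20, 30, 40)])
        assert fit.params["slope"] == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.0)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(SingularFitError):
            fit_linear([(10, 40), (10, 41), (10, 42)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([(10, 40), (20, 41)])

    def test_slope_recovery_within_three_se(self):
        """Generator truth (slope −0.05, σ 0.5, n 25) is recovered."""
        pts = sample_points(
            GCModel("linear", a=43.0, b=-0.05), np.linspace(20, 60, 25), 0.5, 42
        )
        fit = fit_linear(pts)
        se = fit.stderr["slope"]
        assert abs(fit.params["slope"] - (-0.05)) < 3 * se

    def test_r2_invariant_under_size_rescaling(self):
        pts = sample_points(
            GCModel("linear", a=43.0, b=-0.05), np.linspace(20, 60, 25), 0.5, 7
        )
        fit_mb = fit_linear(pts)
        fit_bp = fit_linear([(x * 1e6, y) for x, y in pts])
        assert fit_bp.r_squared == pytest.approx(fit_mb.r_squared, rel=1e-9)
        assert fit_bp.params["slope"] == pytest.approx(
            fit_mb.params["slope"] / 1e6, rel=1e-9
        )


class TestHyperbolicFit:
    def test_exact_hyperbola(self):
        x = np.array([5.0, 10.0, 20.0, 50.0, 100.0])
        fit = fit_hyperbolic(list(zip(x, 40.0 + 100.0 / x)))
        assert fit.params["a"] == pytest.approx(40.0)
        assert fit.params["b"] == pytest.approx(100.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        fit = fit_hyperbolic([(x, 40.0) for x in (10, 20, 40)])
        assert fit.params["b"] == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(0.0)

    def test_parameter_recovery_avian_like(self):
        pts = sample_points(
            GCModel("hyperbolic", a=41.0, b=120.0),
            np.geomspace(5, 200, 30), 0.4, 11,
        )
        fit = fit_hyperbolic(pts)
        assert abs(fit.params["a"] - 41.0) < 3 * fit.stderr["a"]
        assert abs(fit.params["b"] - 120.0) < 3 * fit.stderr["b"]


class TestBreakpoint:
    def test_noise_free_recovery(self):
        model = GCModel("segmented", a=40.0, b=-0.8, breakpoint_mb=50.0)
        sizes = np.concatenate([np.linspace(5, 45, 10), np.linspace(55, 200, 10)])
        pts = list(zip(sizes, model.gc_at(sizes)))
        seg = estimate_breakpoint(pts)
        assert seg.params["breakpoint_mb"] == pytest.approx(50.0, rel=0.05)
        assert seg.params["slope_below"] == pytest.approx(-0.8, abs=0.02)
        assert seg.params["slope_above"] == pytest.approx(0.0, abs=0.02)

    def test_grid_search_rss_is_minimal(self):
        """The reported breakpoint attains the smallest RSS over the whole
        candidate grid, checked by independent re-evaluation."""
        pts = sample_points(
            GCModel("segmented", a=40.0, b=-0.8, breakpoint_mb=50.0),
            np.concatenate([np.geomspace(5, 48, 12), np.linspace(54, 200, 10)]),
            0.3, 5,
        )
        seg = estimate_breakpoint(pts)
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        xs = np.unique(x)
        for bp in (xs[:-1] + xs[1:]) / 2:
            if (x < bp).sum() < 3 or (x >= bp).sum() < 3:
                continue
            X = np.column_stack([np.ones_like(x), x, np.maximum(0, x - bp)])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            assert seg.rss <= rss + 1e-9

    def test_infeasible_when_points_one_sided(self):
        pts = [(10 + i, 40.0 - i) for i in range(6)]
        with pytest.raises(SingularFitError):
            estimate_breakpoint(pts, candidate_grid=[5.0])

    def test_linear_data_not_clearly_segmented(self):
        """On noise-free linear data the segmented model cannot beat the
        linear model by more than the ΔAIC evidence margin."""
        pts = _linear_points(n=20)
        lin = fit_linear(pts)
        seg = estimate_breakpoint(pts)
        assert seg.aic > lin.aic - 2


class TestModelComparison:
    def test_constant_data_prefers_null(self):
        pts = [(x, 40.0) for x in np.linspace(10, 60, 25)]
        cmp_ = fit_all(pts)
        assert cmp_.best.kind == "null"
        assert cmp_.label == "none"

    def test_noisy_flat_data_labelled_none_in_most_seeds(self):
        """Flat GC with chromosome-level noise is called 'no association'
        at well above the nominal 95% rate."""
        hits = sum(
            fit_all(
                sample_points(
                    GCModel("constant", a=36.5), np.linspace(37.5, 59.6, 25),
                    0.5, 100 + s,
                )
            ).label == "none"
            for s in range(20)
        )
        assert hits >= 16

    def test_linear_true_data_ranks_linear_first(self):
        pts = _linear_points(n=25)
        cmp_ = compare_models([fit_null(pts), fit_linear(pts), fit_hyperbolic(pts)])
        assert cmp_.best.kind == "linear"
        assert cmp_.label == "negative"

    def test_hyperbolic_true_data_ranks_hyperbolic_first(self):
        pts = sample_points(
            GCModel("hyperbolic", a=41.0, b=120.0),
            np.geomspace(5, 200, 30), 0.4, 3,
        )
        cmp_ = fit_all(pts, include_segmented=False)
        assert cmp_.best.kind == "hyperbolic"
        assert cmp_.label == "negative"


class TestSizeClass:
    def test_classification_and_boundary(self):
        classes = classify_size([5.0, 200.0, 30.0], threshold_mb=30.0)
        assert [c.size_class for c in classes] == ["micro", "macro", "macro"]


def _comp_with_rep(cid, size_mb, rep_median):
    from chromocomp.composition import ChromosomeComposition

    return ChromosomeComposition(
        chromosome=cid, size_mb=size_mb, n_windows=10,
        gc_bp=400, at_bp=600, n_bp=0, rep_gc_bp=100, rep_at_bp=150,
        rep_pct_median_over_windows=rep_median,
    )


class TestRepVsSize:
    def test_size_independent_repeats_give_flat_slope(self):
        rng = np.random.default_rng(9)
        comps = [
            _comp_with_rep(f"c{i}", s, 30.0 + rng.normal(0, 2.0))
            for i, s in enumerate(np.linspace(10, 60, 25))
        ]
        fit = rep_vs_size(comps)
        assert abs(fit.params["slope"]) < 3 * fit.stderr["slope"]

    def test_negative_coupling_detected(self):
        rng = np.random.default_rng(10)
        sizes = np.linspace(10, 60, 25)
        comps = [
            _comp_with_rep(f"c{i}", s, 45.0 - 0.3 * s + rng.normal(0, 2.0))
            for i, s in enumerate(sizes)
        ]
        fit = rep_vs_size(comps)
        assert fit.params["slope"] < 0
        assert fit.f_test_p < 0.05

    def test_single_chromosome_rejected(self):
        with pytest.raises(ValueError):
            rep_vs_size([_comp_with_rep("c1", 30.0, 25.0)])


class TestWindowGcVsRep:
    @staticmethod
    def _window(cid, start, rep_pct, gc_pct):
        eff = 10_000
        rep_bp = int(eff * rep_pct / 100)
        gc_bp = int(eff * gc_pct / 100)
        rep_gc = min(gc_bp, rep_bp // 2)
        return WindowStat(
            cid, start, start + eff, gc_bp, eff - gc_bp, 0, rep_gc, rep_bp - rep_gc
        )

    def test_exact_linear_relation_recovered(self):
        ws = [
            self._window("chr1", i * 10_000, rep, 30.0 + 0.1 * rep)
            for i, rep in enumerate([10, 20, 30, 40, 50])
        ]
        res = window_gc_vs_rep(ws)["chr1"]
        assert res.fit is not None
        assert res.fit.params["slope"] == pytest.approx(0.1, rel=1e-6)
        assert res.median_rep_pct == pytest.approx(30.0)

    def test_constant_rep_flagged_singular(self):
        ws = [
            self._window("chr1", i * 10_000, 25, 35.0 + i) for i in range(5)
        ]
        res = window_gc_vs_rep(ws)["chr1"]
        assert res.fit is None and res.singular

    def test_repeat_gc_offset_sign_matches_slope_sign(self):
        """Sequence simulated with GC-rich repeats shows a positive window
        GC ~ rep% slope, GC-poor repeats a negative one."""
        from chromocomp.composition import window_composition
        from chromocomp.synthetic import SyntheticGenomeSpec, simulate_chromosomes

        for offset, expected_sign in ((8.0, 1), (-8.0, -1)):
            spec = SyntheticGenomeSpec(
                species="s",
                chromosome_sizes_mb=(1.0,),
                gc_model=GCModel("constant", a=42.0),
                gc_sigma=0.0,
                repeat_density=0.4,
                repeat_gc_offset=offset,
                isochore_gc_sd=0.0,
                n_gap_rate_per_mb=0.0,
                seed=21,
            )
            recs, _ = simulate_chromosomes(spec)
            ws = window_composition(recs[0], 10_000)
            res = window_gc_vs_rep(ws)["chr1"]
            assert np.sign(res.fit.params["slope"]) == expected_sign
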