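import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import vegtherm as vt
from conftest import make_trendless_panel


class TestDetrend:
    def test_exact_trend_fully_removed(self):
        y = 300.0 + 0.1 * np.arange(19)
        out, flagged = vt.detrend_if_significant(y)
        assert flagged
        assert np.allclose(out, y.mean(), atol=1e-10)

    def test_constant_series_unchanged(self):
        y = np.full(19, 300.0)
        out, flagged = vt.detrend_if_significant(y)
        assert not flagged and np.array_equal(out, y)

    def test_null_false_positive_rate(self):
        rng = np.random.default_rng(0)
        hits = sum(vt.detrend_if_significant(rng.normal(0, 1, 19))[1]
                   for _ in range(500))
        assert 0.02 <= hits / 500 <= 0.09

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(0, 1, 19) + 0.2 * np.arange(19)
        once, _ = vt.detrend_if_significant(y)
        twice, flagged2 = vt.detrend_if_significant(once)
        assert np.allclose(once, twice, atol=1e-9)


class TestFitEq5:
    def test_exact_linear_system(self):
        panel = make_trendless_panel(1, 19, (-5.0, 0.001, 0.01), 0.0, seed=1,
                                     intercept=2.0)
        fit = vt.fit_eq5(panel.ndvi[0], panel.lst[0], panel.p[0], panel.rs[0])
        assert fit.reason is None
        assert fit.beta_ndvi == pytest.approx(-5.0, abs=1e-9)
        assert fit.beta_p == pytest.approx(0.001, abs=1e-9)
        assert fit.beta_rs == pytest.approx(0.01, abs=1e-9)

    def test_constant_ndvi_missing(self):
        rng = np.random.default_rng(2)
        fit = vt.fit_eq5(np.full(19, 0.5), rng.normal(300, 1, 19),
                         rng.normal(800, 50, 19), rng.normal(250, 10, 19))
        assert fit.reason == "constant regressor"

    def test_too_few_years_missing(self):
        fit = vt.fit_eq5(np.arange(5.0) / 10, np.arange(5.0),
                         np.arange(5.0), np.arange(5.0))
        assert fit.reason == "insufficient complete years"

    def test_ci_coverage_under_noise(self):
        panel = make_trendless_panel(300, 19, (-8.0, -0.002, 0.02), 0.3, seed=3)
        cover = 0
        for i in range(300):
            fit = vt.fit_eq5(panel.ndvi[i], panel.lst[i], panel.p[i], panel.rs[i])
            cover += fit.ci_ndvi[0] <= -8.0 <= fit.ci_ndvi[1]
        assert 0.90 <= cover / 300 <= 0.99


class TestDeltaLST:
    def test_arithmetic(self):
        fit = vt.InterannualFit(0.0, -10.0, 0.0, 0.0, 0.01, (-12, -8), 19,
                                False, False)
        assert vt.delta_lst(fit, 0.5) == pytest.approx(-0.05)
        assert vt.delta_lst(fit, 0.0) == 0.0
        fit0 = vt.InterannualFit(0.0, 0.0, 0.0, 0.0, 0.9, (-1, 1), 19,
                                 False, False)
        assert vt.delta_lst(fit0, 0.5) == 0.0


class TestCoverageByPrecip:
    def test_rows_sum_to_100_and_partition(self):
        n = 200
        rng = np.random.default_rng(4)
        dmap = vt.DeltaLSTMap(
            delta_lst=rng.normal(-0.05, 0.02, n),
            significant=rng.random(n) < 0.5,
            beta_ndvi=rng.normal(-5, 3, n),
            p_ndvi=rng.random(n),
        )
        precip = rng.uniform(100, 1500, n)
        tab = vt.coverage_by_precip(dmap, precip, n_bins=4)
        assert tab["n"].sum() == n
        pops = tab[tab["n"] > 0]
        sums = pops[["warming_pct", "neutral_pct", "cooling_pct"]].sum(axis=1)
        assert np.allclose(sums, 100.0)

    def test_all_cooling_bin(self):
        dmap = vt.DeltaLSTMap(
            delta_lst=np.full(20, -0.1), significant=np.ones(20, bool),
            beta_ndvi=np.full(20, -5.0), p_ndvi=np.full(20, 0.001))
        tab = vt.coverage_by_precip(dmap, np.linspace(100, 900, 20), n_bins=2)
        assert np.allclose(tab["cooling_pct"], 100.0)


class TestCoolingReduction:
    def test_two_valued_identity(self):
        n = 1000
        dry = np.arange(n) < 280
        delta = np.where(dry, -0.05, -0.1)
        s = vt.dryland_cooling_reduction(delta, dry)
        assert s.reduction_mean == pytest.approx(14.0, abs=1e-9)
        assert s.dryland_area_fraction == pytest.approx(28.0)

    def test_no_drylands_zero(self):
        s = vt.dryland_cooling_reduction(np.full(50, -0.1), np.zeros(50, bool))
        assert s.reduction_mean == 0.0 and s.reduction_median == 0.0

    def test_identical_distributions_zero_mean_reduction(self):
        delta = np.full(100, -0.1)
        dry = np.arange(100) < 30
        s = vt.dryland_cooling_reduction(delta, dry)
        assert s.reduction_mean == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(0.05, 0.9), st.floats(0.05, 0.95))
    @settings(max_examples=50, deadline=None)
    def test_closed_form_on_two_valued_maps(self, f, r):
        # reduction_mean = 100 f (1 - r) for dryland fraction f and
        # dry/humid delta ratio r
        n = 400
        n_dry = max(1, int(round(f * n)))
        f_real = n_dry / n
        dry = np.arange(n) < n_dry
        delta = np.where(dry, -0.1 * r, -0.1)
        s = vt.dryland_cooling_reduction(delta, dry)
        assert s.reduction_mean == pytest.approx(100.0 * f_real * (1 - r),
                                                 abs=1e-8)

    def test_scaling_invariance(self):
        # scaling every delta leaves the percent reduction unchanged
        rng = np.random.default_rng(5)
        delta = -np.abs(rng.normal(0.1, 0.03, 200))
        dry = rng.random(200) < 0.3
        a = vt.dryland_cooling_reduction(delta, dry)
        b = vt.dryland_cooling_reduction(3.7 * delta, dry)
        assert a.reduction_mean == pytest.approx(b.reduction_mean, rel=1e-12)
        assert a.reduction_median == pytest.approx(b.reduction_median, rel=1e-12)

    def test_welch_null_calibration_dry_vs_humid(self):
        rng = np.random.default_rng(6)
        hits, trials = 0, 500
        for _ in range(trials):
            delta = rng.normal(-0.1, 0.02, 120)
            dry = np.arange(120) < 40
            s = vt.dryland_cooling_reduction(delta, dry, ttest="dry_vs_humid")
            hits += s.ttest_p < 0.05
        assert 0.03 <= hits / trials <= 0.07


class TestRegionalBreakdown:
    def test_monotone_in_dryland_fraction(self):
        n = 400
        regions = np.r_[np.zeros(200, int), np.ones(200, int)]
        dry = np.r_[np.arange(200) < 20, np.arange(200) < 120]
        delta = np.where(dry, -0.05, -0.1)
        tab = vt.regional_breakdown(delta, regions, dry)
        red = tab.set_index("region")["reduction_mean"]
        assert red[1] > red[0]

    def test_single_region_equals_global(self):
        rng = np.random.default_rng(7)
        delta = -np.abs(rng.normal(0.1, 0.03, 100))
        dry = rng.random(100) < 0.3
        tab = vt.regional_breakdown(delta, np.zeros(100, int), dry)
        s = vt.dryland_cooling_reduction(delta, dry)
        assert tab.loc[0, "reduction_mean"] == pytest.approx(s.reduction_mean)


class TestPanelPipeline:
    def test_planted_dry_humid_ratio(self):
        # dryland beta_NDVI twice as weak; recovered mean dLST ratio ~ the
        # planted ratio of beta x mean NDVI
        sc = vt.generate_scene(vt.SceneConfig(nx=20, ny=10, n_days=1, seed=8))
        dmap = vt.fit_panel(sc.panel)
        mask = vt.dryland_mask(sc.fields.precip_annual)
        mean_dry = np.nanmean(dmap.delta_lst[mask.dryland])
        mean_hum = np.nanmean(dmap.delta_lst[mask.humid])
        ndvi_mean = np.nanmean(sc.panel.ndvi, axis=1)
        planted = (np.mean(sc.truth.beta_ndvi_true[mask.dryland] * 0.01
                           * ndvi_mean[mask.dryland])
                   / np.mean(sc.truth.beta_ndvi_true[mask.humid] * 0.01
                             * ndvi_mean[mask.humid]))
        assert mean_dry / mean_hum == pytest.approx(planted, rel=0.15)
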