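import numpy as np
import pytest

import vegtherm as vt
from vegtherm.conditioning import ConditioningBin


def _bin(ids, theta=0.1025, rs=251.25):
    return ConditioningBin(bin_id=(0, 0), theta_center=theta, rs_center=rs,
                           pixel_ids=np.asarray(ids))


class TestBuildBins:
    def test_floor_tiling(self):
        theta = np.array([0.1000, 0.1049, 0.1060])
        rs = np.array([700.0, 700.0, 700.0])
        bins = vt.build_bins(theta, rs)
        key = {tuple(b.bin_id): set(b.pixel_ids.tolist()) for b in bins}
        assert key[(20, 280)] == {0, 1}   # floor(0.1049/0.005) = 20
        assert key[(21, 280)] == {2}      # floor(0.1060/0.005) = 21

    def test_rs_tiling(self):
        bins = vt.build_bins(np.array([0.1, 0.1]), np.array([700.0, 702.6]))
        ids = sorted(b.bin_id for b in bins)
        assert ids == [(20, 280), (20, 281)]

    def test_membership_honors_half_widths(self, default_scene):
        f = default_scene.fields
        bins = vt.build_bins(f.theta_mean, f.rs_mean)
        for b in bins:
            assert np.all(np.abs(f.theta_mean[b.pixel_ids] - b.theta_center)
                          <= 0.0025 + 1e-12)
            assert np.all(np.abs(f.rs_mean[b.pixel_ids] - b.rs_center)
                          <= 1.25 + 1e-9)
        # pixels belong to exactly one bin
        all_ids = np.concatenate([b.pixel_ids for b in bins])
        assert np.unique(all_ids).size == all_ids.size == f.n_pixels


class TestFitEq1:
    def test_exact_collinear_fit(self, small_cfg):
        fvc = np.array([0.2, 0.4, 0.6])
        rate = np.array([2.0, 1.5, 1.0])
        est = vt.fit_eq1(_bin([0, 1, 2]), fvc, rate, small_cfg)
        assert est.beta_fvc == pytest.approx(-2.5, abs=1e-12)
        assert np.allclose(est.residuals, 0.0, atol=1e-12)

    def test_insufficient_pixels(self):
        with pytest.raises(ValueError, match="insufficient"):
            vt.fit_eq1(_bin([0, 1, 2]), np.arange(3) / 3, np.arange(3.0))

    def test_zero_fvc_variance(self, small_cfg):
        with pytest.raises(ValueError, match="degenerate"):
            vt.fit_eq1(_bin([0, 1, 2]), np.full(3, 0.5), np.arange(3.0), small_cfg)

    def test_null_type_one_error_calibrated(self):
        # planted beta = 0: the p-value should reject at ~ the nominal rate
        rng = np.random.default_rng(0)
        cfg = vt.AnalysisConfig(min_pixels_per_regressor=5)
        n, reps, hits = 30, 400, 0
        b = _bin(np.arange(n))
        for _ in range(reps):
            fvc = rng.uniform(0.2, 0.8, n)
            rate = rng.normal(3.0, 0.5, n)
            if vt.fit_eq1(b, fvc, rate, cfg).p_fvc < 0.05:
                hits += 1
        assert 0.02 <= hits / reps <= 0.09

    def test_ci_covers_planted_effect(self):
        rng = np.random.default_rng(1)
        cfg = vt.AnalysisConfig(min_pixels_per_regressor=5)
        b = _bin(np.arange(30))
        cover = 0
        reps = 300
        for _ in range(reps):
            fvc = rng.uniform(0.2, 0.8, 30)
            rate = 4.0 - 5.0 * fvc + rng.normal(0, 0.3, 30)
            lo, hi = vt.fit_eq1(b, fvc, rate, cfg).ci_fvc
            cover += lo <= -5.0 <= hi
        assert 0.90 <= cover / reps <= 0.99


class TestClassification:
    def test_rules(self):
        est = vt.EffectEstimate(0.0, -0.3, 0.01, (-0.5, -0.1), 30)
        assert vt.classify_effect(est)[0] == "cooling"
        est = vt.EffectEstimate(0.0, 0.2, 0.20, (-0.1, 0.5), 30)
        assert vt.classify_effect(est)[0] == "neutral"
        est = vt.EffectEstimate(0.0, 0.4, 0.001, (0.2, 0.6), 30)
        assert vt.classify_effect(est)[0] == "warming"

    def test_per_step_scaling_is_exactly_tenth(self):
        est = vt.EffectEstimate(0.0, -2.5, 0.01, (-3.0, -2.0), 30)
        assert vt.classify_effect(est)[1] == pytest.approx(-0.25, abs=1e-15)


class TestAreaFractions:
    def _map(self, codes):
        return vt.EffectClassMap(class_code=np.asarray(codes),
                                 beta_per_step=np.zeros(len(codes)))

    def test_equal_weights(self):
        out = vt.area_fractions(self._map([1, 1, 0, 2]))
        assert out == {"cooling": 50.0, "neutral": 25.0, "warming": 25.0}

    def test_all_cooling(self):
        out = vt.area_fractions(self._map([1, 1, 1]))
        assert out["cooling"] == 100.0 and out["warming"] == 0.0

    def test_weighted_and_sums_to_100(self):
        out = vt.area_fractions(self._map([1, 0, 2, -1]),
                                weights=np.array([3.0, 1.0, 1.0, 10.0]))
        assert sum(out.values()) == pytest.approx(100.0)
        assert out["cooling"] == pytest.approx(60.0)


class TestSeasonalSplit:
    def test_even_partition(self):
        s = vt.seasonal_split(np.array([0.1, 0.2, 0.3, 0.4]))
        assert s.low_days.tolist() == [True, True, False, False]

    def test_tie_day_goes_high(self):
        s = vt.seasonal_split(np.array([0.1, 0.2, 0.3]))
        assert s.low_days.tolist() == [True, False, False]
        assert s.high_days.tolist() == [False, True, True]

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            vt.seasonal_split(np.full(10, 0.4))


class TestFitEq2:
    def test_exact_linear_data(self, small_cfg):
        n = 8
        rng = np.random.default_rng(2)
        fvc = rng.uniform(0.2, 0.8, n)
        theta = rng.uniform(0.05, 0.15, n)
        rs = rng.uniform(200, 300, n)
        rate = 1.0 - 3.0 * fvc + 4.0 * theta + 0.01 * rs
        est = vt.fit_eq2(_bin(np.arange(n)), fvc, theta, rs, rate, small_cfg)
        assert est.beta_fvc == pytest.approx(-3.0, abs=1e-9)
        assert est.beta_theta == pytest.approx(4.0, abs=1e-8)
        assert est.beta_rs == pytest.approx(0.01, abs=1e-10)
        assert np.allclose(est.residuals, 0.0, atol=1e-9)

    def test_seasonal_effect_signs_recovered(self, small_cfg):
        # planted beta_FVC differs by season; the fitted difference keeps
        # the planted sign in the presence of orthogonal controls
        rng = np.random.default_rng(3)
        n = 60
        b = _bin(np.arange(n))
        fvc = rng.uniform(0.2, 0.8, n)
        theta = rng.uniform(0.05, 0.15, n)
        rs = rng.uniform(200, 300, n)
        noise = rng.normal(0, 0.2, (2, n))
        rate_high = 2.0 - 5.0 * fvc + 2.0 * theta + 0.002 * rs + noise[0]
        rate_low = 2.0 - 1.0 * fvc + 2.0 * theta + 0.002 * rs + noise[1]
        est_h = vt.fit_eq2(b, fvc, theta, rs, rate_high, small_cfg)
        est_l = vt.fit_eq2(b, fvc, theta, rs, rate_low, small_cfg)
        assert est_h.beta_fvc < est_l.beta_fvc < 0


class TestEnvPercentDifference:
    @pytest.mark.parametrize("seasonal, annual, expected", [
        (0.084, 0.100, -16.0),
        (1.0, 1.0, 0.0),
        (1.12 * 250.0, 250.0, 12.0),
    ])
    def test_examples(self, seasonal, annual, expected):
        assert vt.env_percent_difference(seasonal, annual) == pytest.approx(expected)

    def test_zero_annual_rejected(self):
        with pytest.raises(ValueError):
            vt.env_percent_difference(1.0, 0.0)


class TestInterannualRegression:
    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(4)
        years = 16
        fvc = rng.uniform(0.3, 0.7, years)
        precip = rng.uniform(400, 800, years)
        dtr = 20.0 - 2.0 * fvc + 0.001 * precip + rng.normal(0, 0.05, years)
        est = vt.interannual_fvc_regression(dtr, fvc, precip)
        assert est.ci_fvc[0] <= -2.0 <= est.ci_fvc[1]

    def test_constant_fvc_missing(self):
        assert vt.interannual_fvc_regression(np.arange(16.0),
                                             np.full(16, 0.5)) is None

    def test_too_few_years_missing(self):
        assert vt.interannual_fvc_regression(np.arange(5.0),
                                             np.arange(5.0) / 10) is None


class TestFullSceneRecovery:
    def test_noise_free_scene_exact(self, noisefree_scene):
        sc = noisefree_scene
        cfg = vt.AnalysisConfig(min_pixels_per_regressor=5, min_valid_days=5)
        rates = vt.daily_median_rates(sc.cube)
        annual = vt.annual_mean_rate(rates, cfg.min_valid_days)
        bins = vt.build_bins(sc.fields.theta_mean, sc.fields.rs_mean, cfg)
        cm = vt.run_assessment(bins, sc.fields.fvc_mean, annual,
                               sc.fields.n_pixels, cfg)
        assert cm.estimates
        for b in bins:
            est = cm.estimates[b.bin_id]
            truth = sc.truth.beta_fvc_true[b.pixel_ids[0]]
            assert abs(est.beta_fvc - truth) / abs(truth) < 1e-10

    def test_dtr_and_rate_classifications_agree(self, noisefree_scene):
        # DTR = 6 h x morning rate + const on the piecewise-linear cycle,
        # so both responses give the same per-bin class
        sc = noisefree_scene
        cfg = vt.AnalysisConfig(min_pixels_per_regressor=5, min_valid_days=5)
        rates = vt.daily_median_rates(sc.cube)
        annual = vt.annual_mean_rate(rates, cfg.min_valid_days)
        dtr_annual = np.nanmean(vt.diurnal_range(sc.cube), axis=1)
        bins = vt.build_bins(sc.fields.theta_mean, sc.fields.rs_mean, cfg)
        cm_rate = vt.run_assessment(bins, sc.fields.fvc_mean, annual,
                                    sc.fields.n_pixels, cfg)
        cm_dtr = vt.run_assessment(bins, sc.fields.fvc_mean, dtr_annual,
                                   sc.fields.n_pixels, cfg)
        assert np.array_equal(cm_rate.class_code, cm_dtr.class_code)

    def test_gradient_summary_monotone(self, noisefree_scene):
        sc = noisefree_scene
        cfg = vt.AnalysisConfig(min_pixels_per_regressor=5, min_valid_days=5)
        rates = vt.daily_median_rates(sc.cube)
        annual = vt.annual_mean_rate(rates, cfg.min_valid_days)
        bins = vt.build_bins(sc.fields.theta_mean, sc.fields.rs_mean, cfg)
        cm = vt.run_assessment(bins, sc.fields.fvc_mean, annual,
                               sc.fields.n_pixels, cfg)
        tab = vt.gradient_summary(cm, sc.fields.precip_annual, "precip", n_bins=5)
        # planted effect strengthens (more negative) toward wetter bins
        means = tab["beta_mean"].to_numpy()
        assert np.all(np.diff(means) < 0)

    def test_gradient_summary_landcover_single_class(self, noisefree_scene):
        sc = noisefree_scene
        cm = vt.EffectClassMap(
            class_code=np.ones(sc.fields.n_pixels, dtype=int),
            beta_per_step=np.full(sc.fields.n_pixels, -0.2))
        tab = vt.gradient_summary(cm, np.full(sc.fields.n_pixels, 10),
                                  "landcover")
        assert len(tab) == 1
        assert tab.loc[0, "beta_mean"] == pytest.approx(-0.2)
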