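"""GPD tail model: log-likelihood oracles, MLE recovery, grid-search
cross-check, CI calibration, model comparison, regime discriminant."""

import warnings

import numpy as np
import pytest
from scipy import stats

import fibermorph as fm
from fibermorph.gpd import GeneralizedParetoMLE, LARGE_BUNDLE, SMALL_BUNDLE


def grid_search_mle(x, k_lo=-0.5, k_hi=2.0, s_lo=0.1, s_hi=10.0, step=1e-3):
    """Independent MLE oracle: coarse-to-fine exhaustive scan of the
    (k, sigma) plane at the requested final resolution."""

    def scan(ks, sigmas):
        best = (-np.inf, None, None)
        for k in ks:  # loop k, vectorize sigma via broadcasting
            z = 1.0 + np.multiply.outer(1.0 / sigmas, k * x)  # (ns, n)
            with np.errstate(divide="ignore", invalid="ignore"):
                if abs(k) < 1e-8:
                    ll = -x.size * np.log(sigmas) - np.sum(x) / sigmas
                else:
                    valid = np.min(z, axis=1) > 0
                    ll = np.full(sigmas.size, -np.inf)
                    ll[valid] = -x.size * np.log(sigmas[valid]) - (
                        1.0 + 1.0 / k
                    ) * np.sum(np.log(z[valid]), axis=1)
            i = int(np.argmax(ll))
            if ll[i] > best[0]:
                best = (float(ll[i]), float(k), float(sigmas[i]))
        return best

    coarse_step = 0.02
    _, k0, s0 = scan(
        np.arange(k_lo, k_hi + coarse_step, coarse_step),
        np.arange(s_lo, s_hi + coarse_step, coarse_step),
    )
    ll, k1, s1 = scan(
        np.arange(max(k_lo, k0 - 2 * coarse_step), min(k_hi, k0 + 2 * coarse_step) + step, step),
        np.arange(max(s_lo, s0 - 2 * coarse_step), min(s_hi, s0 + 2 * coarse_step) + step, step),
    )
    return ll, k1, s1


class TestLoglik:
    def test_exponential_density_at_one(self):
        # k -> 0, sigma = 1: log f(1) = -1
        assert np.isclose(fm.gpd_loglik(0.0, 1.0, [1.0]), -1.0)

    def test_unit_shape_density_at_one(self):
        # k = 1, sigma = 1: f(x) = (1 + x)^-2, log f(1) = -2 ln 2
        assert np.isclose(fm.gpd_loglik(1.0, 1.0, [1.0]), -2.0 * np.log(2.0))

    def test_support_violation_returns_neg_inf(self):
        # k < 0 has bounded support x < -sigma/k
        assert fm.gpd_loglik(-0.5, 1.0, [3.0]) == -np.inf
        assert fm.gpd_loglik(0.5, 1.0, [-1.0]) == -np.inf

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            fm.gpd_loglik(0.5, 0.0, [1.0])

    @pytest.mark.parametrize(
        "k,sigma", [(0.0, 1.0), (0.25, 0.7), (0.7199, 2.4), (1.1141, 3.5058), (-0.2, 2.0)]
    )
    def test_matches_reference_log_density(self, k, sigma):
        rng = np.random.default_rng(12)
        x = stats.genpareto.rvs(c=max(k, 0.01), scale=sigma, size=50, random_state=rng)
        if k < 0:
            x = np.minimum(x, -sigma / k * 0.99)
        expect = stats.genpareto.logpdf(x, c=k, scale=sigma).sum()
        assert np.isclose(fm.gpd_loglik(k, sigma, x), expect, rtol=1e-10)

    @pytest.mark.parametrize("k,sigma", [(0.0, 1.5), (0.6, 2.0), (1.2, 3.0)])
    def test_density_integrates_to_one(self, k, sigma):
        # quadrature over the (possibly transformed) support
        from scipy.integrate import quad

        val, _err = quad(
            lambda x: np.exp(fm.gpd_loglik(k, sigma, [x])), 0, np.inf, limit=200
        )
        assert abs(val - 1.0) < 1e-4


class TestFitGPD:
    def test_exponential_data_recovers_zero_shape(self):
        x = fm.sample_gpd(0.0, 3.0, 10**6, seed=7)
        f = fm.fit_gpd(x)
        assert abs(f.shape_k) <= 0.01
        assert abs(f.scale_sigma - 3.0) / 3.0 <= 0.01

    def test_heavy_tail_recovery_at_reported_parameters(self):
        # type I collagen, trichrome-stained, earlier time point:
        # k = 0.7199, sigma = 2.4000
        x = fm.sample_gpd(0.7199, 2.4, 10**6, seed=101)
        f = fm.fit_gpd(x)
        assert abs(f.shape_k - 0.7199) <= 0.02
        assert abs(f.scale_sigma - 2.4) <= 0.05

    def test_matches_grid_search_oracle(self):
        x = fm.sample_gpd(0.6, 2.0, 200, seed=55)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = fm.fit_gpd(x)
        ll_grid, k_grid, s_grid = grid_search_mle(x)
        assert f.loglik >= ll_grid - 1e-6  # MLE at least as good as any grid point
        assert abs(f.shape_k - k_grid) <= 2e-3
        assert abs(f.scale_sigma - s_grid) <= 2e-3

    def test_scale_equivariance(self):
        y = fm.sample_gpd(0.5, 2.0, 50_000, seed=9)
        f1 = fm.fit_gpd(y)
        c = 123.0
        f2 = fm.fit_gpd(c * y)
        assert abs(f2.shape_k - f1.shape_k) < 1e-6
        assert abs(f2.scale_sigma / c - f1.scale_sigma) / f1.scale_sigma < 1e-6

    def test_implied_mean_matches_sample_mean(self):
        # for k < 1 the fitted mean sigma/(1-k) tracks the sample mean
        x = fm.sample_gpd(0.5, 2.0, 10**6, seed=13)
        f = fm.fit_gpd(x)
        implied = f.scale_sigma / (1.0 - f.shape_k)
        assert abs(implied - x.mean()) / x.mean() < 0.02

    @pytest.mark.parametrize(
        "k,sigma",
        [(0.4971, 1.7294), (0.4971, 3.5058), (1.1141, 1.7294), (1.1141, 3.5058)],
    )
    def test_recovery_across_reported_parameter_envelope(self, k, sigma):
        x = fm.sample_gpd(k, sigma, 10**5, seed=211)
        f = fm.fit_gpd(x)
        assert abs(f.shape_k - k) <= 0.03
        assert abs(f.scale_sigma - sigma) / sigma <= 0.02

    def test_cis_contain_point_estimates(self):
        x = fm.sample_gpd(0.7, 2.0, 5000, seed=3)
        f = fm.fit_gpd(x)
        assert f.k_ci95[0] <= f.shape_k <= f.k_ci95[1]
        assert f.sigma_ci95[0] <= f.scale_sigma <= f.sigma_ci95[1]

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fm.fit_gpd([1.0])
        with pytest.raises(ValueError):
            fm.fit_gpd([1.0, -2.0, 3.0] * 50)
        with pytest.warns(UserWarning, match="only n="):
            fm.fit_gpd(fm.sample_gpd(0.5, 2.0, 50, seed=1))

    def test_estimator_api(self):
        est = GeneralizedParetoMLE(k_threshold=0.5)
        x = fm.sample_gpd(0.8, 2.0, 2000, seed=17)
        est.fit(x)
        assert est.regime_ == LARGE_BUNDLE
        assert est.n_ == 2000
        assert np.isfinite(est.score(x))
        params = est.get_params()
        assert params["k_threshold"] == 0.5
        clone = GeneralizedParetoMLE().set_params(**params)
        assert clone.k_threshold == 0.5
        # column-vector input is accepted (sklearn convention)
        est2 = GeneralizedParetoMLE().fit(x.reshape(-1, 1))
        assert np.isclose(est2.shape_, est.shape_)


class TestCompareTailModels:
    def test_heavy_tailed_data_prefers_gpd_decisively(self):
        x = fm.sample_gpd(0.8, 2.0, 10**5, seed=21)
        mc = fm.compare_tail_models(x)
        assert mc.best_model == "gpd"
        assert mc.models["exponential"]["aic"] - mc.models["gpd"]["aic"] > 10

    def test_nested_penalty_on_exponential_data(self):
        x = fm.sample_gpd(0.0, 2.0, 10**5, seed=22)
        mc = fm.compare_tail_models(x)
        diff = mc.models["gpd"]["aic"] - mc.models["exponential"]["aic"]
        assert 0.0 <= diff <= 4.0

    def test_half_normal_data_recognized(self):
        x = np.abs(stats.norm.rvs(scale=2, size=10**5, random_state=np.random.default_rng(23)))
        mc = fm.compare_tail_models(x)
        assert mc.best_model == "half_normal"

    def test_aic_identity_and_ks_reported(self):
        x = fm.sample_gpd(0.5, 2.0, 1000, seed=4)
        mc = fm.compare_tail_models(x)
        for rec in mc.models.values():
            assert np.isclose(rec["aic"], 2 * rec["n_params"] - 2 * rec["loglik"])
            assert 0.0 <= rec["ks_stat"] <= 1.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            fm.compare_tail_models([1.0, 2.0, 3.0])


class TestRegimeCall:
    def test_reported_shape_values_classify_as_expected(self):
        assert fm.classify_by_k(0.7199).call == LARGE_BUNDLE
        assert fm.classify_by_k(0.5522).call == SMALL_BUNDLE

    def test_tie_goes_to_small_bundle_regime(self):
        assert fm.classify_by_k(0.66).call == SMALL_BUNDLE

    def test_accepts_fit_objects_and_custom_threshold(self):
        f = fm.GPDFit(
            shape_k=0.7, scale_sigma=1.0, k_ci95=(0.6, 0.8),
            sigma_ci95=(0.9, 1.1), loglik=0.0, n=100,
        )
        assert fm.classify_by_k(f, k_threshold=0.75).call == SMALL_BUNDLE


class TestCICoverage:
    def test_quick_coverage_sanity(self):
        cov = fm.ci_coverage_check(0.7, 2.0, 800, 120, seed=5)
        assert 0.88 <= cov <= 1.0

    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            fm.ci_coverage_check(0.7, 2.0, 100, 0, seed=1)
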