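import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from dsurf import detection as det
from dsurf.survey_data import truncate_observations


def _hn_sample(n, sigma, w, rng):
    """Distances from a half-normal detection process truncated at w."""
    x = np.abs(rng.normal(0, sigma, size=4 * n + 100))
    x = x[x <= w]
    return x[:n]


def _obs_from_distances(x, **extra):
    df = pd.DataFrame({"perp_distance": x, "group_size": np.ones(len(x), int)})
    for k, v in extra.items():
        df[k] = v
    return df


class TestKeyFunctions:
    def test_half_normal_at_zero(self):
        assert det.g(0.0, 100.0) == 1.0

    def test_half_normal_at_sigma(self):
        assert det.g(100.0, 100.0) == pytest.approx(np.exp(-0.5))

    @pytest.mark.parametrize("b", [1.0, 2.0, 5.0])
    def test_hazard_rate_at_sigma(self, b):
        # closed form at x = sigma for any shape
        assert det.g(100.0, 100.0, key="hazard_rate", b=b) == pytest.approx(1 - np.exp(-1))

    def test_hazard_rate_at_zero(self):
        assert det.g(0.0, 100.0, key="hazard_rate", b=2.0) == 1.0

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            det.g(1.0, 0.0)

    @given(
        sigma=st.floats(10, 500),
        b=st.floats(1, 10),
        key=st.sampled_from(["half_normal", "hazard_rate"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_non_increasing(self, sigma, b, key):
        x = np.linspace(0.0, 1000.0, 200)
        gx = det.g(x, sigma, key=key, b=b)
        assert np.all(np.diff(gx) <= 1e-12)
        assert np.all((gx >= 0) & (gx <= 1))


class TestScaleModel:
    def test_intercept_only_constant_sigma(self):
        X = np.ones((5, 1))
        sigma = det.scale_from_covariates(np.array([np.log(100.0)]), X)
        np.testing.assert_allclose(sigma, 100.0)

    def test_canopy_ratio_from_coefficients(self):
        # published-style coefficients: open effect 0.321, mixed 0.054
        obs = _obs_from_distances([1, 1, 1], canopy=["hardwood", "mixed", "open"])
        X, names = det.build_design(obs, ("canopy",))
        beta = np.array([-1.680, 0.054, 0.321])
        sigma = det.scale_from_covariates(beta, X)
        assert sigma[2] / sigma[0] == pytest.approx(np.exp(0.321))
        assert sigma[1] / sigma[0] == pytest.approx(np.exp(0.054))
        assert names == ["intercept", "canopy[mixed]", "canopy[open]"]

    def test_unseen_level_named_in_error(self):
        obs = _obs_from_distances([1.0], canopy=["bog"])
        with pytest.raises(ValueError, match="bog"):
            det.build_design(obs, ("canopy",))


class TestAverageP:
    def test_perfect_detection_limit(self):
        assert det.average_p(1e9, 350.0)[0] == pytest.approx(1.0)

    def test_half_normal_closed_form_at_sigma_equal_w(self):
        # p = sqrt(pi/2) * erf(1/sqrt(2)) for sigma = w
        expected = np.sqrt(np.pi / 2) * special.erf(1 / np.sqrt(2))
        assert det.average_p(350.0, 350.0)[0] == pytest.approx(expected, rel=1e-10)

    def test_quadrature_node_halving_stability(self):
        nodes32, weights32 = np.polynomial.legendre.leggauss(32)
        w = 350.0
        for sigma in (80.0, 150.0, 400.0):
            x = 0.5 * w * (nodes32 + 1)
            p32 = 0.5 * np.sum(weights32 * det.g(x, sigma))
            p64 = det.average_p(sigma, w)[0]
            assert abs(p64 - p32) < 1e-8

    def test_monotone_in_w_and_sigma(self):
        ws = np.linspace(50, 800, 20)
        ps = [det.average_p(150.0, w, key="hazard_rate", b=2.0)[0] for w in ws]
        assert np.all(np.diff(ps) <= 1e-12)
        sigmas = np.linspace(20, 500, 20)
        ps = det.average_p(sigmas, 350.0)
        assert np.all(np.diff(ps) >= -1e-12)


class TestFitDetection:
    def test_recovers_half_normal_sigma(self):
        rng = np.random.default_rng(0)
        obs = _obs_from_distances(_hn_sample(2000, 150.0, 350.0, rng))
        fit = det.fit_detection(obs, det.DetectionModel(key="half_normal", truncation=350.0))
        sigma_hat = np.exp(fit.beta[0])
        assert sigma_hat == pytest.approx(150.0, rel=0.1)
        assert 0 < fit.p_bar <= 1
        assert np.all((fit.p_i > 0) & (fit.p_i <= 1))
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)

    def test_duplicated_data_doubles_loglik(self):
        rng = np.random.default_rng(2)
        obs = _obs_from_distances(_hn_sample(150, 120.0, 350.0, rng))
        doubled = pd.concat([obs, obs], ignore_index=True)
        f1 = det.fit_detection(obs, det.DetectionModel(key="half_normal", truncation=350.0))
        f2 = det.fit_detection(doubled, det.DetectionModel(key="half_normal", truncation=350.0))
        assert f2.beta[0] == pytest.approx(f1.beta[0], abs=1e-4)
        assert f2.loglik == pytest.approx(2 * f1.loglik, rel=1e-5)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        obs = _obs_from_distances(_hn_sample(200, 150.0, 350.0, rng))
        shuffled = obs.sample(frac=1.0, random_state=0).reset_index(drop=True)
        f1 = det.fit_detection(obs, det.DetectionModel(key="half_normal", truncation=350.0))
        f2 = det.fit_detection(shuffled, det.DetectionModel(key="half_normal", truncation=350.0))
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-6)

    def test_mle_beats_random_draws(self):
        rng = np.random.default_rng(4)
        obs = _obs_from_distances(_hn_sample(200, 150.0, 350.0, rng))
        model = det.DetectionModel(key="hazard_rate", truncation=350.0)
        fit = det.fit_detection(obs, model)
        x = obs["perp_distance"].to_numpy()
        X = np.ones((len(x), 1))
        best = det._neg_loglik(fit.theta, x, X, "hazard_rate", 350.0)
        for _ in range(32):
            theta = np.array([rng.uniform(np.log(20), np.log(500)), rng.uniform(0, np.log(10))])
            assert det._neg_loglik(theta, x, X, "hazard_rate", 350.0) >= best - 1e-6

    def test_too_few_observations(self):
        obs = _obs_from_distances([10.0, 20.0])
        with pytest.raises(det.FitError):
            det.fit_detection(obs, det.DetectionModel(key="half_normal"))

    def test_untruncated_data_rejected(self):
        obs = _obs_from_distances(np.linspace(0, 500, 30))
        with pytest.raises(ValueError, match="truncat"):
            det.fit_detection(obs, det.DetectionModel(key="half_normal", truncation=350.0))

    def test_recovers_canopy_effect(self, sim_mcds):
        sc, res = sim_mcds
        obs = truncate_observations(res["obs"], 350)
        fit = det.fit_detection(
            obs, det.DetectionModel(key="hazard_rate", covariates=("canopy",), truncation=350.0)
        )
        true_open = np.log(sc.sigma_by_canopy["open"] / sc.sigma_by_canopy["hardwood"])
        j = fit.beta_names.index("canopy[open]")
        se = np.sqrt(fit.vcov[j, j])
        assert abs(fit.beta[j] - true_open) < 3 * se


class TestCvm:
    def test_statistic_minimum_closed_form(self):
        # W2 is minimised at u_(i) = (2i-1)/(2n): value 1/(12n)
        n = 25
        u = (2 * np.arange(1, n + 1) - 1) / (2.0 * n)
        res = stats.cramervonmises(u, "uniform")
        assert res.statistic == pytest.approx(1.0 / (12 * n), rel=1e-9)
        rng = np.random.default_rng(0)
        for _ in range(20):
            sample = rng.uniform(size=n)
            assert stats.cramervonmises(sample, "uniform").statistic >= res.statistic

    def test_too_few_observations(self):
        rng = np.random.default_rng(1)
        obs = _obs_from_distances(_hn_sample(50, 150.0, 350.0, rng))
        fit = det.fit_detection(obs, det.DetectionModel(key="half_normal", truncation=350.0))
        with pytest.raises(ValueError):
            det.cvm_gof(fit, obs.iloc[:2])

    def test_pvalue_reasonable_under_truth(self):
        rng = np.random.default_rng(5)
        obs = _obs_from_distances(_hn_sample(300, 150.0, 350.0, rng))
        fit = det.fit_detection(obs, det.DetectionModel(key="half_normal", truncation=350.0))
        assert fit.cvm_p > 0.01


class TestRankAndSelect:
    def _fit(self, aic, k, label):
        model = det.DetectionModel(key="half_normal", truncation=350.0)
        f = det.DetectionFit(
            model=model, beta=np.zeros(1), beta_names=["intercept"], log_b=None,
            loglik=(2 * k - aic) / 2.0, n_params=k, aic=aic, vcov=None,
            p_i=np.array([0.5]), p_bar=0.5, p_bar_se=None,
        )
        f.model = model
        object.__setattr__(f, "_label", label)
        return f

    def test_parsimony_within_window(self):
        f1 = self._fit(100.0, 4, "a")
        f2 = self._fit(100.77, 3, "b")
        assert det.rank_and_select([f1, f2]) is f2

    def test_single_model_selected(self):
        f = self._fit(10.0, 2, "a")
        assert det.rank_and_select([f]) is f

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            det.rank_and_select([])

    @given(
        aics=st.lists(st.floats(0, 50), min_size=1, max_size=8),
        ks=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_oracle(self, aics, ks):
        fits = [
            self._fit(a, ks.draw(st.integers(1, 6), label=f"k{i}"), str(i))
            for i, a in enumerate(aics)
        ]
        chosen = det.rank_and_select(fits)
        # independent oracle: filter by dAIC <= 2, then argmin over (K, AIC)
        best = min(f.aic for f in fits)
        window = [f for f in fits if f.aic - best <= 2.0]
        oracle = min(window, key=lambda f: (f.n_params, f.aic, f.model.label))
        assert chosen.n_params == oracle.n_params
        assert chosen.aic == oracle.aic


def test_all_subsets_enumeration():
    models = det.all_subsets_models(("canopy", "cloud_cover"), keys=("hazard_rate",))
    assert len(models) == 4  # {}, {canopy}, {cloud}, {canopy, cloud}
    both = det.all_subsets_models(("canopy",), keys=("half_normal", "hazard_rate"))
    assert len(both) == 4
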