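import numpy as np
import pandas as pd
import pytest

from conftest import rtweedie
from dsurf import dsm
from dsurf.smooths import build_smooth


class TestSmoothBasis:
    def _rows(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"x": rng.uniform(0, 10, n), "y": rng.uniform(0, 10, n)})

    def test_column_count_is_k_minus_one(self):
        rows = self._rows()
        sm = build_smooth("xy", ["x", "y"], rows, k=20)
        B = sm.basis(rows)
        assert B.shape[1] == 20 - 1
        assert sm.n_cols == B.shape[1]
        sm1 = build_smooth("s", ["x"], rows, k=10)
        assert sm1.basis(rows).shape[1] == 10 - 1

    def test_training_columns_centred(self):
        rows = self._rows()
        sm = build_smooth("xy", ["x", "y"], rows, k=15)
        np.testing.assert_allclose(sm.basis(rows).mean(axis=0), 0.0, atol=1e-9)

    def test_penalty_symmetric_psd(self):
        rows = self._rows()
        sm = build_smooth("xy", ["x", "y"], rows, k=15)
        np.testing.assert_allclose(sm.S, sm.S.T, atol=1e-12)
        assert np.linalg.eigvalsh(sm.S).min() > 0  # shrinkage => strictly positive

    def test_k_reduced_when_data_sparse(self):
        rows = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0] * 10})
        with pytest.warns(UserWarning, match="reduced"):
            sm = build_smooth("s", ["x"], rows, k=30)
        assert sm.k <= 6


class TestFitDsm:
    def _linear_pc_data(self, n=200, slope=0.4, seed=0, phi=0.8, power=1.5):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-2, 2, n)
        mu = np.exp(0.5 + slope * x)
        return pd.DataFrame(
            {
                "segment_id": [f"s{i}" for i in range(n)],
                "PC1": x,
                "effort_area": np.ones(n),
                "n_hat": rtweedie(mu, phi, power, rng),
            }
        )

    def test_intercept_only_equals_sample_mean(self):
        seg = self._linear_pc_data()
        fit = dsm.fit_dsm(seg, dsm.DsmSpec(terms=(), tweedie_power=1.5))
        assert np.exp(fit.beta[0]) == pytest.approx(seg["n_hat"].mean(), rel=1e-8)

    def test_linear_trend_shrinks_to_line(self):
        seg = self._linear_pc_data(n=300, seed=1)
        fit = dsm.fit_dsm(seg, dsm.DsmSpec(terms=("PC1",), k_pc=10, tweedie_power=1.5))
        assert fit.edf_by_term["PC1"] < 2.0  # ~1 for a pure linear effect
        grid = pd.DataFrame({"PC1": np.linspace(-1.5, 1.5, 11)})
        eta = fit.predict_eta(grid)
        slope = np.polyfit(grid["PC1"], eta, 1)[0]
        assert slope == pytest.approx(0.4, abs=0.15)
        # fitted curve is close to the best line
        resid = eta - np.polyval(np.polyfit(grid["PC1"], eta, 1), grid["PC1"])
        assert np.max(np.abs(resid)) < 0.1

    def test_coefficient_recovery_single_replicate(self):
        seg = self._linear_pc_data(n=400, seed=2)
        fit = dsm.fit_dsm(seg, dsm.DsmSpec(terms=("PC1",), tweedie_power=1.5))
        X = fit.design(pd.DataFrame({"PC1": [-1.0, 1.0]}))
        c = X[1] - X[0]
        est = float(c @ fit.beta)
        se = float(np.sqrt(c @ fit.V @ c))
        assert abs(est - 0.8) < 3 * se  # contrast of a 2-unit step

    def test_fitted_total_close_to_response_total(self, fitted_small):
        fit = dsm.fit_dsm(
            fitted_small["segments"], dsm.DsmSpec(terms=("xy", "PC1"), k_xy=15, k_pc=8, tweedie_power=1.5)
        )
        assert fit.fitted().sum() == pytest.approx(fitted_small["segments"]["n_hat"].sum(), rel=0.05)

    def test_row_order_and_translation_invariance(self):
        seg = self._linear_pc_data(n=150, seed=3)
        rng = np.random.default_rng(0)
        seg["x"] = rng.uniform(0, 50, len(seg))
        seg["y"] = rng.uniform(0, 50, len(seg))
        spec = dsm.DsmSpec(terms=("xy", "PC1"), k_xy=12, k_pc=6, tweedie_power=1.5)
        fit1 = dsm.fit_dsm(seg, spec)
        shuffled = seg.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit2 = dsm.fit_dsm(shuffled, spec)
        translated = seg.copy()
        translated["x"] += 1000.0
        translated["y"] -= 500.0
        fit3 = dsm.fit_dsm(translated, spec)
        probe = seg.iloc[:20]
        probe_t = translated.iloc[:20]
        np.testing.assert_allclose(fit2.predict_eta(probe), fit1.predict_eta(probe), atol=1e-4)
        np.testing.assert_allclose(fit3.predict_eta(probe_t), fit1.predict_eta(probe), atol=1e-4)

    def test_all_zero_response_rejected(self):
        seg = self._linear_pc_data()
        seg["n_hat"] = 0.0
        with pytest.raises(dsm.DsmError, match="zero"):
            dsm.fit_dsm(seg, dsm.DsmSpec(terms=("PC1",)))

    def test_too_few_segments_rejected(self):
        seg = self._linear_pc_data(n=10)
        with pytest.raises(dsm.DsmError):
            dsm.fit_dsm(seg, dsm.DsmSpec(terms=("PC1",)))

    def test_nonpositive_offset_rejected(self):
        seg = self._linear_pc_data()
        seg.loc[0, "effort_area"] = 0.0
        with pytest.raises(dsm.DsmError, match="offset"):
            dsm.fit_dsm(seg, dsm.DsmSpec(terms=("PC1",)))

    def test_deviance_zero_at_saturation(self):
        y = np.array([0.5, 2.0, 7.3])
        assert dsm.tweedie_deviance(y, y, 1.5) == pytest.approx(0.0, abs=1e-12)

    def test_noise_term_shrinks(self):
        seg = self._linear_pc_data(n=300, seed=4)
        rng = np.random.default_rng(5)
        seg["PC2"] = rng.standard_normal(len(seg))
        fit = dsm.fit_dsm(seg, dsm.DsmSpec(terms=("PC1", "PC2"), tweedie_power=1.5))
        assert fit.edf_by_term["PC2"] < fit.edf_by_term["PC1"] + 1.0
        # adding the noise term moves the fitted total by little
        fit0 = dsm.fit_dsm(seg, dsm.DsmSpec(terms=("PC1",), tweedie_power=1.5))
        assert fit.fitted().sum() == pytest.approx(fit0.fitted().sum(), rel=0.05)


class TestAllSubsets:
    def test_pool_of_one_gives_two_models(self, fitted_small):
        table, fits, selected = dsm.all_subsets_select(
            fitted_small["segments"], pool=("PC1",),
            spec=dsm.DsmSpec(terms=("PC1",), k_pc=8, tweedie_power=1.5),
        )
        assert len(table) == 2
        assert set(fits) == {(), ("PC1",)}

    def test_row_count_is_power_of_two(self, fitted_small):
        table, fits, _ = dsm.all_subsets_select(
            fitted_small["segments"], pool=("xy", "PC1"),
            spec=dsm.DsmSpec(terms=("xy", "PC1"), k_xy=12, k_pc=8, tweedie_power=1.5),
        )
        assert len(table) == 4

    def test_selection_matches_table_oracle(self, fitted_small):
        table, fits, selected = dsm.all_subsets_select(
            fitted_small["segments"], pool=("xy", "PC1"),
            spec=dsm.DsmSpec(terms=("xy", "PC1"), k_xy=12, k_pc=8, tweedie_power=1.5),
        )
        # independent rule application on the emitted table
        window = table[table["dAIC"] <= 2.0]
        oracle = window.sort_values(["n_terms", "AIC"]).iloc[0]["model"]
        got = "+".join(selected.spec.terms) if selected.spec.terms else "null"
        assert got == oracle

    def test_clear_winner_selected_outright(self):
        # dAIC {0.0, 3.48}: the top model wins even with more terms
        rows = pd.DataFrame(
            {"model": ["a+b", "a"], "n_terms": [2, 1], "AIC": [100.0, 103.48]}
        )
        rows["dAIC"] = rows["AIC"] - rows["AIC"].min()
        window = rows[rows["dAIC"] <= 2.0]
        assert window.sort_values(["n_terms", "AIC"]).iloc[0]["model"] == "a+b"

    def test_empty_pool_rejected(self, fitted_small):
        with pytest.raises(ValueError):
            dsm.all_subsets_select(fitted_small["segments"], pool=())


class TestVariancePropagation:
    def test_zero_detection_vcov_leaves_cv_unchanged(self, fitted_small):
        fit = dsm.fit_dsm(
            fitted_small["segments"],
            dsm.DsmSpec(terms=("xy", "PC1"), k_xy=12, k_pc=8, tweedie_power=1.5),
        )
        det = fitted_small["det"]
        v_backup = det.vcov
        det.vcov = np.zeros_like(v_backup)
        try:
            with pytest.warns(UserWarning, match="singular"):
                dsm.propagate_detection_variance(fit, det, fitted_small["obs"])
            np.testing.assert_allclose(fit.V_prop, fit.V_base)
        finally:
            det.vcov = v_backup

    def test_propagated_cv_matches_delta_combination(self, fitted_small):
        from dsurf.prediction import predict_grid, total_abundance

        spec = dsm.DsmSpec(terms=("xy", "PC1"), k_xy=12, k_pc=8, tweedie_power=1.5)
        fit = dsm.fit_dsm(fitted_small["segments"], spec)
        cells, _ = predict_grid(fit, None, fitted_small["grid"])
        base = total_abundance(fit, cells)
        dsm.propagate_detection_variance(fit, fitted_small["det"], fitted_small["obs"])
        prop = total_abundance(fit, predict_grid(fit, None, fitted_small["grid"])[0])
        combo = np.hypot(base.cv, fit.cv_det_rel)
        assert prop.cv >= base.cv - 1e-12  # never decreases
        assert abs(prop.cv**2 - combo**2) / combo**2 < 0.2

    def test_term_tests_use_propagated_covariance(self, fitted_small):
        spec = dsm.DsmSpec(terms=("xy", "PC1"), k_xy=12, k_pc=8, tweedie_power=1.5)
        fit = dsm.fit_dsm(fitted_small["segments"], spec)
        dsm.propagate_detection_variance(fit, fitted_small["det"], fitted_small["obs"])
        table = dsm.term_significance(fit)
        assert set(table["term"]) == {"xy", "PC1"}
        assert ((table["p_value"] >= 0) & (table["p_value"] <= 1)).all()


class TestTermSignificance:
    def test_zeroed_term_p_near_one(self, fitted_small):
        fit = dsm.fit_dsm(
            fitted_small["segments"],
            dsm.DsmSpec(terms=("xy", "PC1"), k_xy=12, k_pc=8, tweedie_power=1.5),
        )
        fit.beta[fit.term_slices["PC1"]] = 0.0
        table = dsm.term_significance(fit).set_index("term")
        assert table.loc["PC1", "p_value"] > 0.99
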