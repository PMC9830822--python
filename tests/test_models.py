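"""Design matrices, the model grid, PLS/ridge/SVR fits and importance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milknue.models import (
    CalibrationModel,
    ModelSpec,
    PLSModel,
    build_design_matrix,
    enumerate_model_grid,
    first_non_improving,
    fit_calibration,
    importance_rank,
    pls_fit,
    ridge_fit,
    select_n_lv,
    svr_fit,
    svr_fit_compressed,
)
from milknue.preprocess import ScalerState, mask_regions


class TestGridEnumeration:
    def test_48_specs_per_trait(self):
        grid = enumerate_model_grid(["nue_pct"])
        assert len(grid) == 48

    def test_m6_has_three_cells_m1_has_nine(self):
        grid = enumerate_model_grid(["nl_kg"])
        assert sum(s.predictor_set == "M6" for s in grid) == 3
        assert sum(s.predictor_set == "M1" for s in grid) == 9

    def test_m6_requires_no_treatment(self):
        with pytest.raises(ValueError):
            ModelSpec("M6", "msc", "pls", "nue_pct")
        with pytest.raises(ValueError):
            ModelSpec("M1", "none", "pls", "nue_pct")


class TestDesignMatrix:
    @pytest.mark.parametrize(
        "pset,width",
        [("M1", 215), ("M2", 217), ("M3", 218), ("M4", 219), ("M5", 220), ("M6", 9)],
    )
    def test_column_counts_on_default_grid(self, small_t1, pset, width):
        treatment = "none" if pset == "M6" else "original"
        spec = ModelSpec(pset, treatment, "pls", "nue_pct")
        spectra, grid = mask_regions(small_t1.spectra, small_t1.grid)
        X = build_design_matrix(small_t1, spec, spectra, grid)
        assert X.shape == (len(small_t1), width)

    def test_missing_covariate_raises_named_error(self, small_t1):
        ds = small_t1.subset(np.arange(len(small_t1)))
        ds.table = ds.table.drop(columns=["bcs"])
        spec = ModelSpec("M6", "none", "pls", "nue_pct")
        with pytest.raises(KeyError, match="bcs"):
            build_design_matrix(ds, spec)

    def test_parity_group_encoded_binary(self, small_t1):
        spec = ModelSpec("M6", "none", "pls", "nue_pct")
        X = build_design_matrix(small_t1, spec)
        assert set(np.unique(X["parity_group"])) <= {0.0, 1.0}


class TestPLS:
    def test_full_rank_pls_equals_ols(self, rng):
        X = rng.normal(size=(30, 4))
        X -= X.mean(0)
        y = rng.normal(size=30)
        y -= y.mean()
        model = pls_fit(X, y, n_lv=4)
        b_ols = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(model.coef, b_ols, atol=1e-8)

    def test_rank_one_design_recovered_with_one_component(self, rng):
        u = rng.normal(size=25)
        v = rng.normal(size=6)
        X = np.outer(u - u.mean(), v)  # centered rank-1 design
        y = X @ rng.normal(size=6)
        model = pls_fit(X, y, n_lv=1)
        np.testing.assert_allclose(X @ model.coef, y, atol=1e-8)

    def test_matches_reference_implementation(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        for n, p, k in [(6, 4, 2), (20, 10, 4), (20, 10, 7)]:
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            Xc = (X - X.mean(0)) / X.std(0, ddof=1)
            yc = (y - y.mean()) / y.std(ddof=1)
            ours = pls_fit(Xc, yc, n_lv=k)
            ref = sklearn.PLSRegression(n_components=k, scale=False).fit(Xc, yc)
            np.testing.assert_allclose(ours.coef, ref.coef_.ravel(), atol=1e-6)

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValueError):
            pls_fit(rng.normal(size=(10, 3)), np.ones(10), 2)

    def test_coefficients_permute_with_columns(self, rng):
        X = rng.normal(size=(25, 5))
        y = rng.normal(size=25)
        perm = rng.permutation(5)
        b1 = pls_fit(X, y, 3).coef
        b2 = pls_fit(X[:, perm], y, 3).coef
        np.testing.assert_allclose(b1[perm], b2, atol=1e-10)


class TestLVSelection:
    def test_first_non_improving_rule(self):
        assert first_non_improving([5.0, 4.0, 4.2, 3.0]) == 2
        assert first_non_improving([5.0, 4.0, 3.0]) == 3  # strictly decreasing
        assert first_non_improving([3.0, 3.0]) == 1

    def test_noiseless_rank_two_selects_two(self, rng):
        T = rng.normal(size=(120, 2))
        P = rng.normal(size=(2, 10))
        X = T @ P
        y = T @ np.array([1.0, -2.0])
        groups = np.repeat(np.arange(24), 5)
        assert select_n_lv(X, y, max_lv=6, groups=groups, seed=0) == 2


class TestRidge:
    def test_penalty_zero_is_ols(self, rng):
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        np.testing.assert_allclose(
            ridge_fit(X, y, 0.0), np.linalg.solve(X.T @ X, X.T @ y), atol=1e-10
        )

    def test_one_dimensional_hand_case(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([1.0, -1.0])
        assert ridge_fit(X, y, 1.0)[0] == pytest.approx(2.0 / 3.0)

    def test_large_penalty_shrinks_to_zero(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        assert np.max(np.abs(ridge_fit(X, y, 1e9))) < 1e-6

    def test_matches_reference_implementation(self, rng):
        linear_model = pytest.importorskip("sklearn.linear_model")
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20)
        ref = linear_model.Ridge(alpha=1.0, fit_intercept=False).fit(X, y)
        np.testing.assert_allclose(ridge_fit(X, y, 1.0), ref.coef_, atol=1e-6)


class TestSVR:
    def test_compression_dimension_recorded(self, rng):
        X = rng.normal(size=(60, 20))
        y = X[:, 0] + 0.1 * rng.normal(size=60)
        model = svr_fit_compressed(X, y, n_compress=7)
        assert model.n_compress == 7
        assert model.scores(X).shape == (60, 7)

    def test_smooth_single_direction_fits_within_band(self, rng):
        X = rng.normal(size=(200, 5))
        y = np.tanh(X[:, 0])
        model = svr_fit(X, y, C=1.0, epsilon=0.1)
        rmse = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rmse <= 0.2  # twice the insensitivity band

    def test_deterministic_refit(self, rng):
        X = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        p1 = svr_fit(X, y).predict(X)
        p2 = svr_fit(X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)


class TestImportance:
    def _model_with_coef(self, coef, columns):
        pls = PLSModel(
            weights=np.zeros((1, len(coef))),
            loadings=np.zeros((1, len(coef))),
            y_loadings=np.zeros(1),
            coef=np.asarray(coef, dtype=float),
            coef_path=[np.asarray(coef, dtype=float)],
            n_lv=1,
        )
        return CalibrationModel(
            spec=ModelSpec("M6", "none", "pls", "nue_pct"),
            mask=None,
            masked_grid=None,
            msc_reference=None,
            x_scaler=ScalerState(np.zeros(len(coef)), np.ones(len(coef))),
            y_mean=0.0,
            y_sd=1.0,
            columns=list(columns),
            model=pls,
        )

    def test_ranking_by_absolute_coefficient(self):
        m = self._model_with_coef([0.5, -2.0, 0.0], ["a", "b", "c"])
        ranked = importance_rank(m)
        assert ranked["predictor"].tolist() == ["b", "a", "c"]

    def test_all_zero_keeps_input_order(self):
        m = self._model_with_coef([0.0, 0.0, 0.0], ["a", "b", "c"])
        assert importance_rank(m)["predictor"].tolist() == ["a", "b", "c"]

    def test_non_pls_model_rejected(self, rng):
        m = self._model_with_coef([1.0], ["a"])
        m.model = np.array([1.0])  # ridge-style coefficients
        with pytest.raises(TypeError):
            importance_rank(m)

    def test_planted_band_channels_rank_high(self, t1_dataset):
        model = fit_calibration(t1_dataset, ModelSpec("M1", "original", "pls", "dmi_a_kg"), seed=0)
        top = importance_rank(model)["predictor"].head(10)
        wavenumbers = top.astype(float).to_numpy()
        # urea bands at 1160/1460 carry the intake signal in the generator
        near_band = np.abs(wavenumbers[:, None] - np.array([1160.0, 1460.0])) < 30.0
        assert near_band.any()


class TestCalibrationEndToEnd:
    @pytest.mark.parametrize("algorithm", ["pls", "rr", "svr"])
    def test_fit_predict_shapes_and_determinism(self, small_t1, algorithm):
        spec = ModelSpec("M2", "snv", algorithm, "nue_pct")
        m1 = fit_calibration(small_t1, spec, seed=1)
        m2 = fit_calibration(small_t1, spec, seed=1)
        p1, p2 = m1.predict(small_t1), m2.predict(small_t1)
        assert p1.shape == (len(small_t1),)
        np.testing.assert_array_equal(p1, p2)

    def test_predictions_on_trait_scale(self, small_t1):
        spec = ModelSpec("M2", "msc", "pls", "nue_pct")
        pred = fit_calibration(small_t1, spec, seed=1).predict(small_t1)
        truth = small_t1.table["nue_pct"]
        assert abs(pred.mean() - truth.mean()) < truth.std()
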