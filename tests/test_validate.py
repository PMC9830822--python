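"""Validation metrics, MSPE decomposition and the two validation engines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from milknue.models import ModelSpec, fit_calibration
from milknue.validate import (
    metrics,
    mspe_decompose,
    run_external,
    run_within_herd,
    split_within_herd,
)


class TestSplit:
    def test_eight_cows_quarter_fraction_two_test_cows(self):
        plan = split_within_herd(np.array([f"C{i}" for i in range(8)]), 0.25, 5, seed=0)
        for test, train in plan.repeats:
            assert len(test) == 2 and len(train) == 6
            assert set(test).isdisjoint(train)

    def test_no_cow_on_both_sides(self):
        ids = np.repeat([f"C{i}" for i in range(12)], 4)  # several records per cow
        plan = split_within_herd(ids, 0.25, 5, seed=3)
        for test, train in plan.repeats:
            assert not set(test) & set(train)

    def test_deterministic_given_seed(self):
        ids = np.array([f"C{i}" for i in range(20)])
        a = split_within_herd(ids, seed=9)
        b = split_within_herd(ids, seed=9)
        for (t1, _), (t2, _) in zip(a.repeats, b.repeats):
            assert np.array_equal(t1, t2)

    def test_too_few_cows_rejected(self):
        with pytest.raises(ValueError):
            split_within_herd(np.array(["A", "B", "C"]))


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = metrics(y, y)
        assert m["r2"] == pytest.approx(1.0)
        assert m["re"] == pytest.approx(0.0)
        assert m["spear_r"] == pytest.approx(1.0)

    def test_reversed_order_spearman_minus_one(self):
        y = np.array([10.0, 20.0, 30.0])
        m = metrics(y[::-1], y)
        assert m["spear_r"] == pytest.approx(-1.0)

    def test_hand_computed_rmspe_and_re(self):
        y = np.array([10.0, 20.0, 30.0])
        x = np.array([12.0, 18.0, 33.0])
        m = metrics(x, y)
        assert m["rmspe"] == pytest.approx(np.sqrt(17 / 3), abs=1e-4)
        assert m["re"] == pytest.approx(np.sqrt(17 / 3) / 20.0, abs=1e-4)

    def test_constant_truths_rejected(self):
        with pytest.raises(ValueError):
            metrics(np.array([1.0, 2.0, 3.0]), np.full(3, 5.0))


class TestMSPEDecomposition:
    def test_perfect_prediction_all_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        d = mspe_decompose(y, y)
        assert d.degenerate
        assert (d.bias_pct, d.slope_pct, d.random_pct) == (0.0, 0.0, 100.0)

    def test_pure_offset_is_all_bias(self):
        y = np.array([1.0, 2.0, 3.0])
        x = y + 0.1
        d = mspe_decompose(x, y)
        assert d.mspe == pytest.approx(0.01)
        assert d.error_bias == pytest.approx(0.01)
        assert d.error_slope == pytest.approx(0.0, abs=1e-15)
        assert d.error_random == pytest.approx(0.0, abs=1e-15)

    @settings(max_examples=100, deadline=None)
    @given(
        x=hnp.arrays(np.float64, 20, elements=st.floats(-50, 50)),
        y=hnp.arrays(np.float64, 20, elements=st.floats(-50, 50)),
    )
    def test_components_sum_to_mspe_and_are_nonnegative(self, x, y):
        # scope to well-scaled data: the identity is exact in reals but float
        # cancellation wrecks it when spreads differ by ~100 orders of magnitude
        if np.std(x) < 1e-3 or np.std(y) < 1e-3:
            return
        d = mspe_decompose(x, y)
        total = d.error_bias + d.error_slope + d.error_random
        assert d.error_bias >= 0 and d.error_slope >= 0 and d.error_random >= 0
        if d.mspe > 1e-10:
            # near-perfect agreement leaves the terms with O(eps * variance)
            # rounding, so allow a small absolute floor besides the relative one
            assert total == pytest.approx(d.mspe, rel=1e-6, abs=1e-10)
            assert d.bias_pct + d.slope_pct + d.random_pct == pytest.approx(
                100.0, rel=1e-6, abs=100.0 * 1e-10 / d.mspe
            )

    def test_large_independent_gaussians_identity(self, rng):
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        d = mspe_decompose(x, y)
        direct = np.mean((x - y) ** 2)
        assert d.error_bias + d.error_slope + d.error_random == pytest.approx(direct, rel=1e-10)


class TestREScaleInvariance:
    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(0.01, 100.0))
    def test_re_unchanged_under_joint_rescale(self, scale):
        y = np.array([10.0, 20.0, 30.0, 40.0])
        x = np.array([12.0, 18.0, 33.0, 39.0])
        assert metrics(x * scale, y * scale)["re"] == pytest.approx(metrics(x, y)["re"])


class TestWithinHerd:
    def test_report_shape_and_sd_over_repeats(self, small_t1):
        spec = ModelSpec("M6", "none", "rr", "nue_pct")
        rep = run_within_herd(small_t1, [spec], n_repeats=5, seed=0)
        assert len(rep) == 1
        assert rep["r2_sd"][0] >= 0

    def test_noiseless_linear_trait_near_perfect(self, small_t1):
        ds = small_t1.subset(np.arange(len(small_t1)))
        # plant a trait that is an exact linear function of M6 covariates
        ds.table = ds.table.copy()
        ds.table["nue_pct"] = 2.0 * ds.table["my_kg"] + 0.5 * ds.table["mun_mg_dl"]
        rep = run_within_herd(ds, [ModelSpec("M6", "none", "rr", "nue_pct")], seed=0)
        assert rep["r2_mean"][0] > 0.99

    def test_identical_seeds_identical_reports(self, small_t1):
        spec = ModelSpec("M2", "snv", "pls", "nue_pct")
        a = run_within_herd(small_t1, [spec], seed=5)
        b = run_within_herd(small_t1, [spec], seed=5)
        assert a.equals(b)

    def test_record_order_invariance(self, t1_dataset, rng):
        spec = ModelSpec("M6", "none", "rr", "nue_pct")
        shuffled = t1_dataset.subset(rng.permutation(len(t1_dataset))).canonicalize()
        a = run_within_herd(t1_dataset, [spec], seed=2)
        b = run_within_herd(shuffled, [spec], seed=2)
        assert np.allclose(a["r2_mean"], b["r2_mean"])


class TestExternal:
    def test_training_set_as_external_reproduces_in_sample_metrics(self, small_t1):
        spec = ModelSpec("M2", "msc", "pls", "nue_pct")
        model = fit_calibration(small_t1, spec, seed=0)
        overall, _ = run_external([model], small_t1)
        pred = model.predict(small_t1)
        truth = small_t1.table["nue_pct"].to_numpy()
        assert overall["r2"][0] == pytest.approx(metrics(pred, truth)["r2"])

    def test_report_has_group_rows_with_gh(self, small_t1, t2_dataset):
        spec = ModelSpec("M2", "msc", "pls", "nue_pct")
        model = fit_calibration(small_t1, spec, seed=0)
        overall, per_group = run_external([model], t2_dataset)
        assert len(overall) == 1
        assert len(per_group) == 3
        assert (per_group["mean_gh"] > 0).all()

    def test_grid_mismatch_rejected(self, small_t1, t2_dataset):
        import numpy as np
        from milknue.data import Dataset, SpectrumGrid

        spec = ModelSpec("M1", "original", "pls", "nue_pct")
        model = fit_calibration(small_t1, spec, seed=0)
        bad_grid = SpectrumGrid(t2_dataset.grid.wavenumbers + 0.5)
        bad = Dataset(t2_dataset.table, t2_dataset.spectra, bad_grid, dict(t2_dataset.diets))
        with pytest.raises(ValueError):
            model.predict(bad)
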