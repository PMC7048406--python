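"""Regression families, error metrics and the train/test/hold-out split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import grassinvert as gi
from grassinvert.errors import DomainError
from grassinvert.regress import FAMILIES

from conftest import normal_equations_ols


class TestSplit:
    def test_canonical_split_sizes(self):
        ids = [f"Q{i:04d}" for i in range(173)]
        split = gi.split_data(ids, (153, 20, 115), seed=3)
        assert len(split.model_ids) == 153
        assert len(split.holdout_ids) == 20
        assert len(split.train_ids) == 115
        assert len(split.test_ids) == 38

    def test_partition_is_exhaustive_and_disjoint(self):
        ids = list(range(173))
        split = gi.split_data(ids, (153, 20, 115), seed=3)
        assert sorted(split.model_ids + split.holdout_ids) == sorted(ids)
        assert sorted(split.train_ids + split.test_ids) == sorted(split.model_ids)

    def test_reproducible_under_seed(self):
        ids = list(range(50))
        a = gi.split_data(ids, (40, 10, 30), seed=9)
        b = gi.split_data(ids, (40, 10, 30), seed=9)
        assert a == b
        c = gi.split_data(ids, (40, 10, 30), seed=10)
        assert a.train_ids != c.train_ids

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            gi.split_data(list(range(100)), (153, 20, 115), seed=0)


class TestMetrics:
    def test_perfect_prediction_gives_zero(self):
        assert gi.standard_error([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert gi.mec([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_single_point_standard_error(self):
        assert gi.standard_error([100.0], [80.0]) == pytest.approx(20.0)

    def test_standard_error_direct_arithmetic(self):
        assert gi.standard_error([3.0, 4.0], [0.0, 0.0]) == pytest.approx(np.sqrt(25 / 2))

    def test_mec_direct_arithmetic(self):
        assert gi.mec([100.0, 200.0], [90.0, 220.0]) == pytest.approx(10.0)

    def test_mec_scale_invariance(self):
        y, yp = np.array([80.0, 120.0, 150.0]), np.array([90.0, 100.0, 180.0])
        assert gi.mec(y, yp) == pytest.approx(gi.mec(7.3 * y, 7.3 * yp))

    def test_zero_measured_value_rejected(self):
        with pytest.raises(DomainError):
            gi.mec([0.0, 1.0], [1.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gi.standard_error([1.0], [1.0, 2.0])


class TestFitFamily:
    def test_exact_exponential_recovery(self):
        x = np.linspace(0.2, 0.9, 20)
        y = 12.523 * np.exp(3.370 * x)
        fit = gi.fit_family(x, y, "exponential")
        assert fit.coef_a == pytest.approx(12.523, rel=1e-9)
        assert fit.coef_b == pytest.approx(3.370, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_exact_linear_recovery(self):
        x = np.linspace(0.0, 1.0, 10)
        fit = gi.fit_family(x, 2 * x + 1, "linear")
        assert fit.coef_a == pytest.approx(2.0)
        assert fit.coef_b == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_exact_power_and_logarithmic_recovery(self):
        x = np.linspace(0.2, 0.9, 15)
        p = gi.fit_family(x, 299.611 * x**2.216, "power")
        assert p.coef_a == pytest.approx(299.611, rel=1e-9)
        assert p.coef_b == pytest.approx(2.216, rel=1e-9)
        lg = gi.fit_family(x, 284.562 * np.log(x) + 248.525, "logarithmic")
        assert lg.coef_a == pytest.approx(284.562, rel=1e-9)
        assert lg.coef_b == pytest.approx(248.525, rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_linear_ols_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 11)
        x = rng.uniform(0.1, 1.0, n)
        y = rng.uniform(10.0, 300.0, n)
        slope, intercept = normal_equations_ols(x, y)
        fit = gi.fit_family(x, y, "linear")
        assert fit.coef_a == pytest.approx(slope, rel=1e-10)
        assert fit.coef_b == pytest.approx(intercept, rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("family", ["logarithmic", "power", "exponential"])
    def test_transformed_fits_match_transformed_oracle(self, family, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 11))
        x = rng.uniform(0.1, 1.0, n)
        y = rng.uniform(10.0, 300.0, n)
        fit = gi.fit_family(x, y, family)
        if family == "logarithmic":
            slope, intercept = normal_equations_ols(np.log(x), y)
            a, b = slope, intercept
        elif family == "power":
            slope, intercept = normal_equations_ols(np.log(x), np.log(y))
            a, b = np.exp(intercept), slope
        else:
            slope, intercept = normal_equations_ols(x, np.log(y))
            a, b = np.exp(intercept), slope
        assert fit.coef_a == pytest.approx(a, rel=1e-10)
        assert fit.coef_b == pytest.approx(b, rel=1e-10)

    def test_nonlinear_refinement_moves_fit_on_noisy_data(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0.2, 0.9, 50)
        y = 12.0 * np.exp(3.0 * x) * (1 + rng.normal(0, 0.2, 50))
        plain = gi.fit_family(x, y, "exponential")
        refined = gi.fit_family(x, y, "exponential", refine=True)
        # refinement minimizes original-scale SSE, so its R^2 cannot be worse
        assert refined.r2 >= plain.r2 - 1e-12

    def test_log_required_domains_enforced(self):
        x_bad = np.array([-0.1, 0.2, 0.5, 0.8])
        y = np.array([10.0, 20.0, 40.0, 80.0])
        for family in ("logarithmic", "power"):
            with pytest.raises(DomainError):
                gi.fit_family(x_bad, y, family)
        with pytest.raises(DomainError):
            gi.fit_family(np.abs(x_bad), np.array([-1.0, 20.0, 40.0, 80.0]), "exponential")

    @given(seed=st.integers(0, 1000))
    def test_adjusted_r2_below_r2_for_imperfect_fits(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 1.0, 20)
        y = rng.uniform(10.0, 300.0, 20)
        fit = gi.fit_family(x, y, "linear")
        if fit.r2 < 1.0:
            assert fit.adj_r2 < fit.r2


class TestCompareFamilies:
    @staticmethod
    def _frame(x, y):
        return pd.DataFrame(
            {"quadrat_id": range(len(x)), "plot_id": 0, "soc_ndvi": x, "agb_g_m2": y}
        )

    def test_noiseless_linear_data_selects_linear(self):
        x = np.linspace(0.1, 0.9, 60)
        y = 200 * x + 50
        comp = gi.compare_families(self._frame(x[:40], y[:40]), self._frame(x[40:], y[40:]))
        assert comp.selected == "linear"
        assert comp.fits["linear"].r2 == pytest.approx(1.0)

    def test_exponential_law_with_noise_usually_selects_exponential(self):
        wins = 0
        n_runs = 12
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.25, 0.9, 153)
            y = np.maximum(12.523 * np.exp(3.370 * x) * (1 + rng.normal(0, 0.2, 153)), 1.0)
            comp = gi.compare_families(self._frame(x[:115], y[:115]), self._frame(x[115:], y[115:]))
            wins += comp.selected == "exponential"
        assert wins >= n_runs * 2 / 3

    def test_table_layout_families_by_statistics(self):
        x = np.linspace(0.1, 0.9, 40)
        y = 12.0 * np.exp(3.0 * x)
        comp = gi.compare_families(self._frame(x[:30], y[:30]), self._frame(x[30:], y[30:]))
        table = comp.table()
        assert list(table.columns) == list(FAMILIES)
        assert set(table.index) == {"equation", "n", "r2", "adj_r2", "se_g_m2", "mec_percent"}

    def test_unfittable_family_recorded_not_fatal(self):
        x = np.array([-0.2, 0.1, 0.4, 0.7, 0.9, 0.95])  # negative x kills log families
        y = 12.0 * np.exp(3.0 * x)
        comp = gi.compare_families(self._frame(x[:4], y[:4]), self._frame(x[4:], y[4:]))
        assert {"logarithmic", "power"} <= set(comp.failures)
        assert comp.selected in ("linear", "exponential")
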