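"""Annual means, stratification proxy, WLF, log transform, PCA, PERMANOVA."""

import numpy as np
import pandas as pd
import pytest

from lakeddg.env import (
    annual_means,
    build_env_records,
    log_transform,
    pca_drivers,
    representativeness_check,
    tempsd,
    wlf,
    wlf_from_series,
)
from lakeddg.io import ENV_VARIABLES, WaterLevelStats


def monthly_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["lake_id", "year", "month", "variable", "measure_depth_m", "value", "below_detection"],
    )


class TestAnnualMeans:
    def test_seven_months_is_missing(self):
        m = monthly_frame([("L1", 2010, i, "P_tot", 0.0, 0.01, False) for i in range(1, 8)])
        assert np.isnan(annual_means(m, "L1", 2010)["P_tot"])

    def test_below_detection_counts_as_zero(self):
        m = monthly_frame([("L1", 2010, i, "NH4", 0.0, 0.02, True) for i in range(1, 13)])
        assert annual_means(m, "L1", 2010)["NH4"] == 0.0

    def test_eight_equal_values_give_their_mean(self):
        m = monthly_frame([("L1", 2010, i, "Cond", 0.0, 2.0, False) for i in range(1, 9)])
        assert annual_means(m, "L1", 2010)["Cond"] == pytest.approx(2.0)

    def test_month_order_irrelevant_and_below_detection_never_raises_mean(self):
        rows = [("L1", 2010, i, "NO3", 0.0, float(i), False) for i in range(1, 10)]
        m1 = annual_means(monthly_frame(rows), "L1", 2010)["NO3"]
        m2 = annual_means(monthly_frame(rows[::-1]), "L1", 2010)["NO3"]
        assert m1 == m2
        rows.append(("L1", 2010, 10, "NO3", 0.0, 50.0, True))  # flagged -> counts 0
        m3 = annual_means(monthly_frame(rows), "L1", 2010)["NO3"]
        assert m3 <= m1


class TestTempsd:
    def _strat_rows(self, temps, months=range(1, 9)):
        rows = []
        for mo in months:
            for d, v in zip((0.0, -2.0, -4.0, -6.0), temps):
                rows.append(("L1", 2010, mo, "Temp", d, v, False))
        return monthly_frame(rows)

    def test_identical_depths_give_zero(self):
        assert tempsd(self._strat_rows([15, 15, 15, 15]), "L1", 2010) == 0.0

    def test_hand_computed_monthly_sd(self):
        # sd of {20, 18, 12, 10} = sqrt(68/3) = 4.76 (2 dp)
        val = tempsd(self._strat_rows([20, 18, 12, 10]), "L1", 2010)
        assert val == pytest.approx(4.76, abs=0.005)

    def test_stronger_stratification_raises_tempsd(self):
        weak = tempsd(self._strat_rows([16, 15, 14, 13]), "L1", 2010)
        strong = tempsd(self._strat_rows([22, 18, 10, 6]), "L1", 2010)
        assert strong > weak

    def test_missing_depth_series_gives_nan(self):
        rows = self._strat_rows([20, 18, 12, 10])
        rows = rows[rows["measure_depth_m"] != -6.0]
        assert np.isnan(tempsd(rows, "L1", 2010))


class TestWLF:
    def test_formula(self):
        assert wlf(WaterLevelStats("L1", 2.0, 1.5)) == pytest.approx(0.5)

    def test_constant_level_is_zero(self):
        assert wlf(WaterLevelStats("L1", 1.0, 1.0)) == 0.0

    def test_corrupt_stats_rejected(self):
        with pytest.raises(ValueError, match="MHW"):
            WaterLevelStats("L1", 1.0, 2.0)

    def test_gauge_series_annual_extremes(self):
        levels = pd.DataFrame(
            {"year": [2010] * 2 + [2011] * 2 + [2012] * 2, "level_m": [2, 1, 3, 1, 4, 1]}
        )
        # MHW = mean(2,3,4) = 3; MLW = mean(1,1,1) = 1
        assert wlf_from_series(levels) == pytest.approx(2.0)


class TestLogTransform:
    def test_unit_value_maps_to_zero_without_zeros(self):
        t = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        assert log_transform(t)["x"].iloc[0] == pytest.approx(0.0)

    def test_zero_column_offset_is_half_min_positive(self):
        t = pd.DataFrame({"x": [0.0, 2.0]})
        out = log_transform(t)["x"]
        assert out.iloc[0] == pytest.approx(np.log(1.0))
        assert out.iloc[1] == pytest.approx(np.log(3.0))

    def test_ph_exempt(self):
        t = pd.DataFrame({"pH": [8.1, 8.3]})
        pd.testing.assert_frame_equal(log_transform(t), t)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            log_transform(pd.DataFrame({"x": [-1.0, 2.0]}))


class TestPCA:
    def test_correlated_pair_and_independent_variable_split_axes(self):
        # a noisy pair shares the first axis; the independent variable gets
        # its own axis (note: for exactly two standardized variables the
        # eigenvectors always sit at 45 degrees, so separation needs >= 3)
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 4000)
        t = pd.DataFrame(
            {"a": x, "b": x + rng.normal(0, 0.3, 4000), "c": rng.normal(0, 1, 4000)}
        )
        res = pca_drivers(t)
        assert res.axis_names[0] == ["a", "b"]
        assert res.axis_names[1] == ["c"]

    def test_two_independent_variables_halve_the_variance(self):
        rng = np.random.default_rng(10)
        t = pd.DataFrame({"a": rng.normal(0, 1, 4000), "b": rng.normal(0, 1, 4000)})
        res = pca_drivers(t)
        assert res.explained[0] == pytest.approx(0.5, abs=0.05)

    def test_duplicated_variable_shares_first_axis(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 400)
        t = pd.DataFrame({"a": x, "b": x + rng.normal(0, 1e-6, 400), "c": rng.normal(0, 1, 400)})
        res = pca_drivers(t)
        assert {"a", "b"} <= set(res.axis_names[0])

    def test_explained_fractions_sum_to_one_and_decrease(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(rng.normal(0, 1, (60, 5)), columns=list("abcde"))
        res = pca_drivers(t)
        assert res.explained.sum() == pytest.approx(1.0)
        assert all(np.diff(res.explained) <= 1e-12)

    def test_retained_prefix_exceeds_variance_target(self):
        rng = np.random.default_rng(3)
        t = pd.DataFrame(rng.normal(0, 1, (60, 6)), columns=list("abcdef"))
        res = pca_drivers(t)
        cum = np.cumsum(res.explained)
        assert cum[res.n_retained - 1] > 0.80
        assert res.n_retained == 1 or cum[res.n_retained - 2] <= 0.80

    def test_reconstruction_of_standardized_table(self):
        rng = np.random.default_rng(4)
        t = pd.DataFrame(rng.normal(0, 1, (30, 4)), columns=list("abcd"))
        res = pca_drivers(t)
        Z = (t.to_numpy() - res.mean) / res.scale
        full_scores = Z @ res.loadings.to_numpy()
        back = full_scores @ res.loadings.to_numpy().T
        assert np.allclose(back, Z, atol=1e-8)

    def test_constant_variable_named_in_error(self):
        t = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.raises(ValueError, match="'a'"):
            pca_drivers(t)

    def test_too_few_records_rejected(self):
        t = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 1, 3]})
        with pytest.raises(ValueError, match=">= 5"):
            pca_drivers(t)


class TestRepresentativeness:
    def test_shifted_subset_maximally_separated(self):
        rng = np.random.default_rng(0)
        full = pd.DataFrame(rng.normal(0, 1, (30, 3)), columns=list("abc"))
        shifted = full.iloc[:10] + [10.0, 0, 0]
        f, p = representativeness_check(shifted, full.iloc[10:], n_perm=199, seed=1)
        assert p <= 1 / 200 + 1e-9

    def test_random_split_pseudo_f_near_one(self):
        rng = np.random.default_rng(1)
        full = pd.DataFrame(rng.normal(0, 1, (60, 3)), columns=list("abc"))
        f, p = representativeness_check(full.iloc[:30], full.iloc[30:], n_perm=199, seed=2)
        assert 0.2 < f < 3.0
        assert p > 0.05  # representative

    def test_mismatched_columns_rejected(self):
        a = pd.DataFrame({"x": [1.0, 2]})
        b = pd.DataFrame({"y": [1.0, 2]})
        with pytest.raises(ValueError, match="columns"):
            representativeness_check(a, b)


def test_build_env_records_assembles_all_driver_columns():
    rows = []
    for i in range(1, 13):
        for var in ENV_VARIABLES:
            rows.append(("L1", 2010, i, var, 0.0, 5.0, False))
        for d in (-2.0, -4.0, -6.0):
            rows.append(("L1", 2010, i, "Temp", d, 5.0, False))
    monthly = monthly_frame(rows)
    from conftest import make_meta

    recs = build_env_records(
        monthly, {"L1": make_meta()}, {"L1": WaterLevelStats("L1", 2.0, 1.4)}, [("L1", 2010)]
    )
    row = recs.iloc[0]
    assert row["WLF"] == pytest.approx(0.6)
    assert row["Tempsd"] == 0.0
    assert row["Cond"] == pytest.approx(5.0)
    assert not recs.drop(columns=["lake_id", "year"]).isna().any().any()
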