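"""The virtual lake system: determinism, closed-form expectations, drifts."""

import numpy as np
import pandas as pd
import pytest

from lakeddg.depths import MIDPOINTS
from lakeddg.io import filter_records
from lakeddg.partition import all_profiles
from lakeddg.synthetic import (
    NicheSpec,
    SimulationConfig,
    generate_lake_system,
    generate_temporal_series,
)


def small_config(**kw):
    base = dict(
        seed=1,
        n_lakes=3,
        n_transects_per_lake=3,
        years=(2010, 2013, 2016),
        species_pool_size=25,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestNicheSpec:
    def test_presence_prob_peaks_at_optimum(self):
        s = NicheSpec("sp", -3.0, 1.0, 0.8)
        assert s.presence_prob(-3.0) == pytest.approx(0.8)
        assert s.presence_prob(-1.5) < s.presence_prob(-3.0)
        assert s.presence_prob(-3.0 - 1.0) == pytest.approx(0.8 * np.exp(-0.5))


class TestGenerateLakeSystem:
    def test_same_seed_gives_identical_output(self):
        a = generate_lake_system(small_config())
        b = generate_lake_system(small_config())
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[3], b[3])
        assert a[4].expected_peak_depth == b[4].expected_peak_depth

    def test_different_seed_differs(self):
        a = generate_lake_system(small_config())
        b = generate_lake_system(small_config(seed=2))
        assert not a[0].equals(b[0])

    def test_degenerate_niche_confined_to_one_class(self):
        cfg = small_config(
            optimum_mean=-1.5,
            optimum_sd=0.0,
            tolerance_mean=0.05,
            tolerance_sd=0.0,
            lake_access_prob=1.0,
        )
        surveys, *_, truth = generate_lake_system(cfg)
        assert set(surveys["depth_class"]) == {"1-2"}
        assert all(v == -1.5 for v in truth.expected_peak_depth.values())

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            small_config(species_pool_size=0)

    def test_generated_records_survive_filtering(self):
        surveys, metas, _, _, _ = generate_lake_system(small_config(seed=5))
        filtered, log = filter_records(surveys, metas)
        # deep/natural/dimictic lakes, all submerged species-rank records
        assert log.rows_removed.get("lake_gate", 0) == 0
        assert log.rows_removed.get("growth_form", 0) == 0
        assert log.rows_removed.get("not_species_rank", 0) == 0

    def test_expected_gamma_dominates_expected_alpha(self):
        # union over transects can only add species relative to the mean
        cfg = small_config(seed=9)
        surveys, metas, _, _, truth = generate_lake_system(cfg)
        filtered, _ = filter_records(surveys, metas)
        for p in all_profiles(filtered):
            for d in MIDPOINTS:
                assert p.gamma[d] >= p.alpha[d] - 1e-12

    def test_monte_carlo_alpha_matches_closed_form(self):
        # all niches identical: optimum -3, tol 1, max prob 0.8, full affinity
        cfg = SimulationConfig(
            seed=42,
            n_lakes=1,
            n_transects_per_lake=50,
            years=(2010,),
            species_pool_size=20,
            optimum_mean=-3.0,
            optimum_sd=0.0,
            tolerance_mean=1.0,
            tolerance_sd=0.0,
            max_presence_prob_range=(0.8, 0.8),
            lake_access_prob=1.0,
            affinity_range=(1.0, 1.0),
        )
        surveys, _, _, _, truth = generate_lake_system(cfg)
        counts = (
            surveys.groupby(["transect_id", "depth_class"])["taxon"].nunique().unstack(fill_value=0)
        )
        spec = NicheSpec("s", -3.0, 1.0, 0.8)
        label_of = {-0.5: "0-1", -1.5: "1-2", -3.0: "2-4", -5.0: ">4"}
        for d in MIDPOINTS:
            p = spec.presence_prob(d)
            expected = 20 * p
            se = np.sqrt(20 * p * (1 - p) / 50)
            observed = counts.get(label_of[d], pd.Series(0, index=counts.index)).mean()
            assert abs(observed - expected) <= 3 * max(se, 1e-9) + 1e-9
            assert truth.expected_alpha["L01"][d] == pytest.approx(expected)

    def test_monthly_series_has_missing_months_and_detection_flags(self):
        cfg = small_config(seed=3, missing_month_prob=0.2, below_detection_quantile=0.5)
        monthly = generate_lake_system(cfg)[3]
        per = monthly.groupby(["lake_id", "year", "variable", "measure_depth_m"])["month"].count()
        assert per.min() < 12  # some months dropped
        assert monthly["below_detection"].any()
        # temperature present at the four stratification depths
        tdepths = set(monthly[monthly["variable"] == "Temp"]["measure_depth_m"])
        assert tdepths == {0.0, -2.0, -4.0, -6.0}


class TestTemporalSeries:
    def test_requires_three_years(self):
        with pytest.raises(ValueError, match="3 survey years"):
            generate_temporal_series(small_config(years=(2010, 2012)))

    def test_zero_drift_truth_signs_are_zero(self):
        _, truth = generate_temporal_series(small_config())
        assert truth.trend_signs["d_alpha_max"] == 0
        assert truth.trend_signs["total_gamma"] == 0

    def test_positive_optimum_drift_flagged_shallower(self):
        _, truth = generate_temporal_series(small_config(optimum_drift=0.5))
        assert truth.trend_signs["d_alpha_max"] == 1

    def test_pool_growth_raises_gamma_over_years(self):
        cfg = small_config(seed=21, pool_drift=3.0, years=(2010, 2012, 2014, 2016))
        surveys, truth = generate_temporal_series(cfg)
        assert truth.trend_signs["total_gamma"] == 1
        gam = surveys.groupby("year")["taxon"].nunique()
        assert gam.iloc[-1] > gam.iloc[0]
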