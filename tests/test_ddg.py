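"""Peak measures (D_max, R_max), tie handling, and pattern classification."""

import numpy as np
import pandas as pd
import pytest

from lakeddg.ddg import (
    classify_pattern,
    ddg_alpha_measures,
    ddg_profile_measures,
    pattern_frequencies,
    pattern_table,
    transect_peak,
)
from lakeddg.depths import DEPTH_MIDPOINTS

from conftest import make_records


class TestTransectPeak:
    def test_unique_argmax(self):
        assert transect_peak({-0.5: 2, -1.5: 5, -3.0: 4, -5.0: 1}) == (-1.5, 5)

    def test_two_way_tie_averages_midpoints(self):
        # equal species numbers in two depths -> mean of the two midpoints
        assert transect_peak({-0.5: 1, -1.5: 5, -3.0: 5, -5.0: 0}) == (-2.25, 5)

    def test_uniform_counts_average_all_four(self):
        assert transect_peak({-0.5: 1, -1.5: 1, -3.0: 1, -5.0: 1}) == (-2.5, 1)

    def test_all_zero_transect_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            transect_peak({-0.5: 0, -1.5: 0, -3.0: 0, -5.0: 0})


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "d,pattern",
        [
            (-0.5, "decreasing"),
            (-1.5, "shallow_hump"),
            (-3.0, "deep_hump"),
            (-5.0, "increasing"),
        ],
    )
    def test_pure_midpoints_map_to_the_four_classes(self, d, pattern):
        assert classify_pattern(d) == pattern

    @pytest.mark.parametrize(
        "d,pattern",
        [(-1.0, "shallow_hump"), (-2.0, "deep_hump"), (-4.0, "increasing")],
    )
    def test_boundaries_go_to_the_deeper_class(self, d, pattern):
        assert classify_pattern(d) == pattern

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern(-5.5)
        with pytest.raises(ValueError):
            classify_pattern(0.0)


class TestAlphaMeasures:
    def test_mean_of_transect_peaks(self):
        rows = (
            # T1 peaks at -1.5 with 2 species; T2 at -3.0 with 3
            [("T1", "1-2", s) for s in "AB"]
            + [("T1", "0-1", "A")]
            + [("T2", "2-4", s) for s in "ABC"]
            + [("T2", "0-1", "A")]
        )
        m = ddg_alpha_measures(make_records(rows), "L1", 2010)
        assert m.d_max == pytest.approx(-2.25)
        assert m.r_max == pytest.approx(2.5)

    def test_identical_transects_equal_single_peak(self):
        rows = [(t, "2-4", s) for t in ("T1", "T2") for s in "AB"]
        m = ddg_alpha_measures(make_records(rows), "L1", 2010)
        assert (m.d_max, m.r_max) == (-3.0, 2.0)
        assert m.pattern == "deep_hump"

    def test_empty_transects_excluded_and_counted(self):
        # T2 appears only via a genus record -> empty after presence counting?
        # here: T2 simply has records at no depth (absent entirely) is not a
        # transect; instead give T2 zero species by filtering upstream. The
        # relevant case: a transect whose rows are all at other campaigns.
        rows = [("T1", "1-2", "A"), ("T1", "1-2", "B"), ("T2", "0-1", "C")]
        m = ddg_alpha_measures(make_records(rows), "L1", 2010)
        assert m.n_empty_transects == 0
        assert m.d_max == pytest.approx((-1.5 + -0.5) / 2)

    def test_transect_order_invariance(self):
        rows = [("T1", "1-2", "A"), ("T2", "2-4", "B"), ("T3", "0-1", "C")]
        rec = make_records(rows)
        m1 = ddg_alpha_measures(rec, "L1", 2010)
        m2 = ddg_alpha_measures(rec.iloc[::-1].reset_index(drop=True), "L1", 2010)
        assert (m1.d_max, m1.r_max) == (m2.d_max, m2.r_max)

    def test_r_max_is_mean_of_transect_maxima_not_peak_of_mean_profile(self):
        # T1: 3 species at -0.5; T2: 3 species at -3.0. Mean profile peaks
        # at 1.5 (both depths); per-transect maxima average to 3.
        rows = [("T1", "0-1", s) for s in "ABC"] + [("T2", "2-4", s) for s in "DEF"]
        m = ddg_alpha_measures(make_records(rows), "L1", 2010)
        assert m.r_max == 3.0  # the alternative reading would give 1.5


class TestProfileMeasures:
    def test_gamma_profile_peak(self):
        m = ddg_profile_measures({-0.5: 8, -1.5: 11, -3.0: 9, -5.0: 2}, "gamma")
        assert (m.d_max, m.r_max) == (-1.5, 11.0)
        assert m.pattern == "shallow_hump"

    def test_strictly_decreasing_profile(self):
        m = ddg_profile_measures({-0.5: 9, -1.5: 7, -3.0: 3, -5.0: 1}, "beta")
        assert m.d_max == -0.5
        assert m.pattern == "decreasing"

    def test_deep_tie_classifies_increasing_under_boundary_rule(self):
        m = ddg_profile_measures({-0.5: 1, -1.5: 2, -3.0: 5, -5.0: 5}, "gamma")
        assert m.d_max == -4.0
        assert m.pattern == "increasing"

    def test_all_zero_profile_rejected(self):
        with pytest.raises(ValueError):
            ddg_profile_measures({-0.5: 0, -1.5: 0, -3.0: 0, -5.0: 0}, "gamma")


class TestPatternFrequencies:
    def _measures(self, records):
        from lakeddg.ddg import all_measures

        return all_measures(records)

    def test_single_pattern_dominates(self):
        rec = make_records([("T1", "0-1", "A"), ("T2", "0-1", "B")])
        freqs = pattern_frequencies(self._measures(rec), "alpha")
        assert freqs["decreasing"] == 100.0
        assert sum(freqs.values()) == pytest.approx(100.0)

    def test_even_split(self):
        rec = pd.concat(
            [
                make_records([("T1", "1-2", "A"), ("T2", "1-2", "B")], "L1", 2010),
                make_records([("T1", "2-4", "A"), ("T2", "2-4", "B")], "L1", 2013),
            ],
            ignore_index=True,
        )
        freqs = pattern_frequencies(self._measures(rec), "alpha")
        assert freqs["shallow_hump"] == 50.0 and freqs["deep_hump"] == 50.0

    def test_pattern_table_shape(self):
        rec = make_records([("T1", "0-1", "A"), ("T2", "0-1", "B")])
        tab = pattern_table(self._measures(rec))
        assert tab.shape == (3, 4)
        assert tab.loc["alpha", "decreasing"] == 1


def test_classified_midpoints_cover_all_four_patterns():
    patterns = {classify_pattern(d) for d in DEPTH_MIDPOINTS.values()}
    assert patterns == {"decreasing", "shallow_hump", "deep_hump", "increasing"}
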