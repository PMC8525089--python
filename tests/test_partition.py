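"""Additive richness partitioning against hand enumeration and a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from lakeddg.depths import DEPTH_LABELS, MIDPOINTS
from lakeddg.partition import (
    all_profiles,
    alpha_profile,
    beta_profile,
    gamma_profile,
    richness_profile,
    total_gamma,
)

from conftest import make_records


def brute_force_partition(records: pd.DataFrame):
    """Independent oracle: explicit set enumeration per depth class.

    Every transect of the campaign contributes a (possibly empty) species
    set to every depth class; alpha is the mean set size, gamma the union
    size, beta the difference.
    """
    from lakeddg.depths import depth_midpoint

    transects = sorted(records["transect_id"].unique())
    alpha, gamma, beta = {}, {}, {}
    for lab, mid in zip(DEPTH_LABELS, MIDPOINTS):
        sets = []
        for t in transects:
            sel = records[(records["transect_id"] == t) & (records["depth_class"] == lab)]
            sets.append(set(sel["taxon"]))
        alpha[mid] = sum(len(s) for s in sets) / len(sets)
        gamma[mid] = len(set().union(*sets)) if sets else 0
        beta[mid] = gamma[mid] - alpha[mid]
    total = len(set(records["taxon"]))
    return alpha, gamma, beta, total


class TestHandExamples:
    def test_shared_species_toy(self, toy_campaign):
        # T1={A,B}, T2={B,C} at -0.5: alpha 2, gamma 3, beta 1
        a = alpha_profile(toy_campaign, "L1", 2010)
        g = gamma_profile(toy_campaign, "L1", 2010)
        b = beta_profile(a, g)
        assert a[-0.5] == 2.0 and g[-0.5] == 3 and b[-0.5] == 1.0

    def test_species_in_one_of_two_transects_gives_half(self):
        rec = make_records([("T1", "1-2", "A"), ("T2", "0-1", "B")])
        assert alpha_profile(rec, "L1", 2010)[-1.5] == 0.5

    def test_identical_transects_have_zero_beta(self):
        rec = make_records(
            [("T1", "0-1", "A"), ("T1", "2-4", "B"), ("T2", "0-1", "A"), ("T2", "2-4", "B")]
        )
        p = richness_profile(rec, "L1", 2010)
        assert all(p.beta[d] == 0 for d in MIDPOINTS)
        assert all(p.alpha[d] == p.gamma[d] for d in MIDPOINTS)

    def test_disjoint_transects_beta_is_half_gamma(self):
        rec = make_records([("T1", "0-1", "A"), ("T2", "0-1", "B")])
        p = richness_profile(rec, "L1", 2010)
        assert p.beta[-0.5] == 1.0 == p.gamma[-0.5] / 2

    def test_empty_depth_class_has_zero_gamma(self, toy_campaign):
        assert gamma_profile(toy_campaign, "L1", 2010)[-5.0] == 0

    def test_total_gamma_counts_each_species_once(self, toy_campaign):
        assert total_gamma(toy_campaign, "L1", 2010) == 3
        dup = pd.concat(
            [toy_campaign, make_records([("T1", "2-4", "A")])], ignore_index=True
        )
        assert total_gamma(dup, "L1", 2010) == 3

    def test_absent_campaign_raises(self, toy_campaign):
        with pytest.raises(ValueError, match="no records"):
            alpha_profile(toy_campaign, "L1", 1999)

    def test_mismatched_profiles_raise(self):
        with pytest.raises(ValueError, match="different campaigns"):
            beta_profile({-0.5: 3.0}, {-0.5: 1})  # negative beta impossible in-campaign


def _random_campaign(rng: np.random.Generator) -> pd.DataFrame:
    n_tr = rng.integers(2, 5)
    n_sp = rng.integers(1, 7)
    rows = []
    for t in range(n_tr):
        for lab in DEPTH_LABELS:
            for s in range(n_sp):
                if rng.random() < 0.35:
                    rows.append((f"T{t}", lab, f"sp{s}"))
    if not rows:  # ensure a non-empty campaign
        rows.append(("T0", "0-1", "sp0"))
        rows.append(("T1", "0-1", "sp0"))
    return make_records(rows)


@pytest.mark.parametrize("seed", range(5))
def test_matches_brute_force_oracle_on_random_campaigns(seed):
    rng = np.random.default_rng(seed)
    for _ in range(40):
        rec = _random_campaign(rng)
        a, g, b, tot = brute_force_partition(rec)
        p = richness_profile(rec, "L1", 2010)
        assert p.alpha == pytest.approx(a)
        assert p.gamma == g
        assert p.beta == pytest.approx(b)
        assert p.total_gamma == tot


def test_additivity_and_monotonicity():
    rng = np.random.default_rng(99)
    rec = _random_campaign(rng)
    p = richness_profile(rec, "L1", 2010)
    # alpha + beta = gamma exactly (mean of integers is exact in binary)
    for d in MIDPOINTS:
        assert p.alpha[d] + p.beta[d] == p.gamma[d]
        assert p.beta[d] >= 0
    # adding a record never decreases gamma or total gamma
    extra = pd.concat([rec, make_records([("T0", ">4", "novel")])], ignore_index=True)
    q = richness_profile(extra, "L1", 2010)
    assert all(q.gamma[d] >= p.gamma[d] for d in MIDPOINTS)
    assert q.total_gamma >= p.total_gamma


def test_all_profiles_covers_each_campaign_once():
    rec = pd.concat(
        [
            make_records([("T1", "0-1", "A"), ("T2", "0-1", "B")], "L1", 2010),
            make_records([("T1", "0-1", "A"), ("T2", "1-2", "B")], "L2", 2012),
        ],
        ignore_index=True,
    )
    profs = all_profiles(rec)
    assert {(p.lake_id, p.year) for p in profs} == {("L1", 2010), ("L2", 2012)}
    assert all(p.n_transects == 2 for p in profs)
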