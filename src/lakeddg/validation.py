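"""Simulation studies validating each pipeline stage against known truth.

Each study regenerates its inputs from a seed, runs the corresponding
pipeline stage, and scores it against an independent oracle or the
generator's closed-form truth:

* additive partitioning vs brute-force set enumeration on toy campaigns;
* alpha-peak recovery on lake systems whose expected peak depth is known;
* familywise error of the robust max-t depth contrasts on null data, and
  agreement with classical Tukey HSD (studentized range) on an exactly
  homoscedastic fixture;
* stepwise additive-model selection: spurious-axis elimination under a
  null response, retention of a genuine smooth effect, and the
  single-term drop-contribution identity;
* trend-sign recovery under injected drifts and the flagging rate under a
  permuted-year null.

The studies are consumed by the acceptance harness and by targeted tests;
their default sizes are the study conditions, not tuning knobs.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .ddg import ddg_alpha_measures
from .depths import DEPTH_LABELS, MIDPOINTS, depth_midpoint
from .depth_stats import robust_depth_comparisons
from .gamm import fit_gamm
from .io import SURVEY_COLUMNS, WaterLevelStats
from .partition import richness_profile
from .synthetic import SimulationConfig, generate_lake_system
from .trends import invariability


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


# ---------------------------------------------------------------------------
# 1. partitioning vs brute force
# ---------------------------------------------------------------------------

def _enumerate_partition(records: pd.DataFrame):
    """Brute-force oracle: explicit per-depth set enumeration."""
    transects = sorted(records["transect_id"].unique())
    alpha, gamma = {}, {}
    for lab in DEPTH_LABELS:
        mid = depth_midpoint(lab)
        sets = [
            set(records[(records["transect_id"] == t) & (records["depth_class"] == lab)]["taxon"])
            for t in transects
        ]
        alpha[mid] = sum(len(s) for s in sets) / len(sets)
        gamma[mid] = len(set().union(*sets))
    beta = {d: gamma[d] - alpha[d] for d in alpha}
    return alpha, gamma, beta, len(set(records["taxon"]))


def partition_oracle_study(n_campaigns: int = 1000, seed: int = 0) -> dict[str, float]:
    """Random toy campaigns (<= 4 transects, <= 6 species) vs enumeration."""
    rng = np.random.default_rng(seed)
    matches = 0
    beta_ok = 0
    for _ in range(n_campaigns):
        n_tr = int(rng.integers(2, 5))
        n_sp = int(rng.integers(1, 7))
        rows = [
            (f"T{t}", lab, f"sp{s}")
            for t in range(n_tr)
            for lab in DEPTH_LABELS
            for s in range(n_sp)
            if rng.random() < 0.35
        ]
        if not rows:
            rows = [("T0", "0-1", "sp0"), ("T1", "0-1", "sp0")]
        rec = pd.DataFrame(
            [("L1", 2010, t, lab, sp, "species", "submerged", 1) for t, lab, sp in rows],
            columns=SURVEY_COLUMNS,
        )
        a, g, b, tot = _enumerate_partition(rec)
        p = richness_profile(rec, "L1", 2010)
        exact = (
            all(abs(p.alpha[d] - a[d]) < 1e-12 for d in MIDPOINTS)
            and all(p.gamma[d] == g[d] for d in MIDPOINTS)
            and all(abs(p.beta[d] - b[d]) < 1e-12 for d in MIDPOINTS)
            and p.total_gamma == tot
        )
        matches += exact
        beta_ok += all(p.beta[d] >= 0 for d in MIDPOINTS)
    return {
        "match_pct": 100.0 * matches / n_campaigns,
        "beta_nonnegative_pct": 100.0 * beta_ok / n_campaigns,
    }


# ---------------------------------------------------------------------------
# 2. alpha-peak recovery on synthetic lakes
# ---------------------------------------------------------------------------

def _peak_config(seed: int) -> SimulationConfig:
    """One deep lake whose expected alpha profile peaks at -3.0 m."""
    return SimulationConfig(
        seed=seed,
        n_lakes=1,
        n_transects_per_lake=10,
        years=(2010,),
        species_pool_size=20,
        optimum_mean=-3.0,
        optimum_sd=0.0,
        tolerance_mean=1.0,
        tolerance_sd=0.0,
        max_presence_prob_range=(0.8, 0.8),
        lake_access_prob=1.0,
        affinity_range=(0.5, 1.0),
    )


def peak_recovery_study(n_seeds: int = 200, seed: int = 0, tol_m: float = 0.75) -> float:
    """Share of replicates with D_(alpha,max) within `tol_m` of the truth."""
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        surveys, _, _, _, truth = generate_lake_system(_peak_config(int(s)))
        m = ddg_alpha_measures(surveys, "L01", 2010)
        hits += abs(m.d_max - truth.expected_peak_depth["L01"]) <= tol_m
    return 100.0 * hits / n_seeds


# ---------------------------------------------------------------------------
# 3. max-t calibration and Tukey HSD agreement
# ---------------------------------------------------------------------------

def maxt_fwer_study(
    n_datasets: int = 2000, n_per_group: int = 25, n_mc: int = 4000, seed: int = 0
) -> float:
    """Familywise rejection rate at alpha = .05 on balanced normal nulls."""
    rejections = 0
    groups = np.repeat(list(MIDPOINTS), n_per_group)
    for s in _child_seeds(seed, n_datasets):
        rng = np.random.default_rng(int(s))
        obs = pd.DataFrame({"depth_m": groups, "value": rng.normal(0, 1, len(groups))})
        res = robust_depth_comparisons(obs, n_mc=n_mc, seed=rng)
        rejections += any(r.p_adjusted < 0.05 for r in res)
    return rejections / n_datasets


def tukey_agreement_study(n_per_group: int = 100, n_mc: int = 200_000, seed: int = 0) -> float:
    """Max |p_maxt - p_TukeyHSD| on an exactly homoscedastic fixture.

    The fixture repeats one standardized residual vector in every group, so
    the classical equal-variance assumption holds exactly and the
    studentized-range computation is a valid oracle.
    """
    rng = np.random.default_rng(seed)
    e = rng.normal(0, 1, n_per_group)
    e = (e - e.mean()) / e.std(ddof=1)
    means = [0.0, 0.35, 0.1, 0.55]
    labels = sorted(MIDPOINTS)  # contrast labels follow ascending group order
    obs = pd.DataFrame(
        {
            "depth_m": np.repeat(labels, n_per_group),
            "value": np.concatenate([m + e for m in means]),
        }
    )
    res = robust_depth_comparisons(obs, n_mc=n_mc, seed=seed + 1)

    # oracle: classical Tukey HSD from the studentized range distribution
    k = len(labels)
    n = k * n_per_group
    groups = [obs.loc[obs["depth_m"] == g, "value"].to_numpy() for g in labels]
    s2 = sum(((g - g.mean()) ** 2).sum() for g in groups) / (n - k)
    oracle = {}
    for a, b in combinations(range(k), 2):
        se = np.sqrt(s2 / n_per_group)  # balanced: sqrt(s2/2*(1/n+1/n))*sqrt2
        q = abs(groups[b].mean() - groups[a].mean()) / np.sqrt(s2 / 2 * (2 / n_per_group))
        oracle[f"{labels[b]} - {labels[a]}"] = stats.studentized_range.sf(q, k, n - k)
    return max(abs(r.p_adjusted - oracle[r.label]) for r in res)


# ---------------------------------------------------------------------------
# 4. stepwise additive-model selection
# ---------------------------------------------------------------------------

def _gamm_frame(seed: int, n: int = 60, n_lakes: int = 6):
    rng = np.random.default_rng(seed)
    lakes = np.repeat([f"L{i}" for i in range(n_lakes)], n // n_lakes)
    df = pd.DataFrame(
        {
            "lake_id": lakes,
            "PC1": rng.uniform(-2, 2, n),
            "PC2": rng.uniform(-2, 2, n),
            "PC3": rng.uniform(-2, 2, n),
        }
    )
    offsets = dict(zip(sorted(set(lakes)), rng.normal(0, 0.5, n_lakes)))
    return df, df["lake_id"].map(offsets).to_numpy(), rng


def gamm_null_elimination_study(n_seeds: int = 200, seed: int = 0) -> float:
    """Share of pure-noise responses for which no axis survives selection."""
    empty = 0
    for s in _child_seeds(seed, n_seeds):
        df, _, rng = _gamm_frame(int(s))
        df["y"] = rng.normal(0, 1, len(df))
        empty += not fit_gamm(df, "y", ["PC1", "PC2", "PC3"]).retained
    return 100.0 * empty / n_seeds


def gamm_retention_study(n_seeds: int = 60, seed: int = 0) -> float:
    """Share of replicates retaining a genuine smooth effect of PC1."""
    kept = 0
    for s in _child_seeds(seed, n_seeds):
        df, offset, rng = _gamm_frame(int(s))
        df["y"] = np.sin(1.5 * df["PC1"]) + offset + rng.normal(0, 0.3, len(df))
        kept += "PC1" in fit_gamm(df, "y", ["PC1", "PC2", "PC3"]).retained
    return 100.0 * kept / n_seeds


def gamm_drop_identity_check(seed: int = 0) -> float:
    """|drop contribution - deviance explained| for a single-term model."""
    df, offset, rng = _gamm_frame(seed)
    df["y"] = np.sin(1.5 * df["PC1"]) + offset + rng.normal(0, 0.3, len(df))
    res = fit_gamm(df, "y", ["PC1"])
    if res.retained != ["PC1"]:
        return float("nan")
    return abs(res.drop_contribution["PC1"] - res.deviance_explained)


# ---------------------------------------------------------------------------
# 5. temporal trends
# ---------------------------------------------------------------------------

def trend_sign_recovery_study(n_seeds: int = 200, seed: int = 0) -> dict[str, float]:
    """Recovered trend signs vs injected drifts.

    Peak-depth drift: niche optima shallow by 0.5 m/yr.  Pool growth:
    two extra species gain lake access per year.
    """
    d_hits = 0
    g_hits = 0
    for s in _child_seeds(seed, n_seeds):
        cfg = SimulationConfig(
            seed=int(s),
            n_lakes=1,
            n_transects_per_lake=4,
            years=(2010, 2011, 2012, 2013, 2014),
            species_pool_size=25,
            optimum_mean=-3.0,
            optimum_sd=0.3,
            lake_access_prob=1.0,
            affinity_range=(0.5, 1.0),
            optimum_drift=0.5,
        )
        surveys, *_ = generate_lake_system(cfg)
        d_by_year = [
            ddg_alpha_measures(surveys, "L01", y).d_max for y in cfg.years
        ]
        slope = stats.linregress(cfg.years, d_by_year).slope
        d_hits += slope > 0

        cfg_g = SimulationConfig(
            seed=int(s) + 1,
            n_lakes=1,
            n_transects_per_lake=4,
            years=(2010, 2011, 2012, 2013, 2014),
            species_pool_size=40,
            lake_access_prob=0.5,
            pool_drift=2.0,
        )
        surveys_g, *_ = generate_lake_system(cfg_g)
        gam = surveys_g.groupby("year")["taxon"].nunique()
        g_hits += stats.linregress(gam.index.to_numpy(float), gam.to_numpy(float)).slope > 0
    return {
        "d_max_sign_pct": 100.0 * d_hits / n_seeds,
        "gamma_sign_pct": 100.0 * g_hits / n_seeds,
    }


def trend_null_study(n_replicates: int = 500, seed: int = 0) -> float:
    """Share of lake-level tests flagged (p < .1) under a permuted-year null."""
    flagged = 0
    total = 0
    for s in _child_seeds(seed, n_replicates):
        rng = np.random.default_rng(int(s))
        cfg = SimulationConfig(
            seed=int(s),
            n_lakes=2,
            n_transects_per_lake=2,
            years=tuple(range(2006, 2021, 2)),
            species_pool_size=40,
        )
        surveys, *_ = generate_lake_system(cfg)
        for lake in ("L01", "L02"):
            gam = (
                surveys[surveys["lake_id"] == lake].groupby("year")["taxon"].nunique()
            )
            years = rng.permutation(gam.index.to_numpy(float))
            p = stats.linregress(years, gam.to_numpy(float)).pvalue
            flagged += p < 0.1
            total += 1
    return 100.0 * flagged / total


# ---------------------------------------------------------------------------
# 6. closed-form checks
# ---------------------------------------------------------------------------

def closed_form_checks() -> dict[str, float]:
    """WLF, IC, the depth-midpoint map, and the midpoint pattern classes."""
    from .ddg import classify_pattern

    wlf_val = WaterLevelStats("L", 2.0, 1.5).wlf_m
    ic_val = invariability(pd.Series([4.0, 5.0, 6.0]), "L", "gamma").ic
    midpoints_ok = [depth_midpoint(lab) for lab in DEPTH_LABELS] == [-0.5, -1.5, -3.0, -5.0]
    patterns_ok = [classify_pattern(d) for d in (-0.5, -1.5, -3.0, -5.0)] == [
        "decreasing",
        "shallow_hump",
        "deep_hump",
        "increasing",
    ]
    return {
        "wlf_m": float(wlf_val),
        "ic": float(ic_val),
        "midpoint_map_exact": float(midpoints_ok),
        "pattern_map_exact": float(patterns_ok),
    }
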