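"""Virtual lake systems with known depth-diversity structure.

Generates the full input suite for the pipeline — survey records, lake
metadata, water-level statistics, monthly physiochemistry — from a simple
stochastic community model whose expectations are known in closed form, so
every downstream stage can be tested against analytic truth.

Community model: each species in a regional pool has a Gaussian depth
niche; its presence probability at signed depth d (m) is

    p(d) = max_presence_prob * exp(-(d - optimum)^2 / (2 * tolerance^2))

scaled by a per-lake affinity in [0, 1].  Presence is an independent draw
per species x transect x depth class; the Kohler frequency is drawn
uniformly from 1..5 given presence.  Overlapping Gaussian niches produce
hump-shaped alpha profiles with expected value

    E[alpha](d) = sum_s affinity_s * p_s(d)

whose argmax over the four class midpoints is recorded as truth.  Between-
transect turnover (beta) arises from the independent draws; the generator
injects no explicit spatial autocorrelation.

Monthly physiochemistry is an annual lake mean plus a seasonal sinusoid
plus Gaussian noise; whole months go missing with a configured
probability, and small values of the trace nutrients fall below the
detection limit (value retained, flag set), exercising the >= 8-month and
zero-substitution rules downstream.  Temperature is generated at 0, -2,
-4, -6 m with a seasonally stratified profile so the Tempsd proxy is
meaningful.

Multi-year series can drift: niche optima shift linearly (m/yr, positive
= shallower) and the species pool grows or shrinks (species/yr); injected
signs are recorded as truth for trend-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .depths import DEPTH_LABELS, MIDPOINTS
from .io import ENV_VARIABLES, LakeMeta, WaterLevelStats

#: Per-variable (low, high) ranges for lake-level annual means, spanning the
#: spread observed in deep perialpine monitoring lakes.
ENV_RANGES: dict[str, tuple[float, float]] = {
    "Chl": (0.3, 15.0),  # chloride mg/l
    "Cond": (160.0, 370.0),  # conductivity uS/cm
    "N_tot": (0.2, 1.2),  # total nitrogen mg/l
    "NH4": (0.0, 0.09),  # ammonium mg/l
    "NO3": (0.0, 1.1),  # nitrate mg/l
    "O2diss": (9.0, 11.5),  # dissolved oxygen mg/l
    "P_tot": (0.0, 0.02),  # total phosphorus mg/l
    "pH": (8.0, 8.5),
    "SiO2": (0.0, 2.9),  # silicate mg/l
    "Temp": (9.5, 19.5),  # surface temperature degC
    "Transp": (240.0, 1200.0),  # transparency cm^-1
    "SAC": (0.0, 25.0),  # spectral absorption 254 nm 1/m
}

#: Trace variables whose low values fall below the detection limit.
_DETECTION_LIMITED = ("NH4", "NO3", "P_tot", "SiO2", "SAC")


@dataclass(frozen=True)
class NicheSpec:
    """Gaussian depth niche of one species."""

    species_id: str
    optimum_depth: float  # m, negative downward
    tolerance: float  # m, > 0
    max_presence_prob: float  # in [0, 1]

    def presence_prob(self, depth: float) -> float:
        z = (depth - self.optimum_depth) / self.tolerance
        return self.max_presence_prob * float(np.exp(-0.5 * z * z))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the virtual lake system.

    Defaults emulate a state monitoring programme: 28 deep natural
    dimictic lakes, a 75-species regional pool, a handful of transects per
    lake, three survey years, and monthly physiochemistry with roughly one
    month in ten missing.
    """

    seed: int  # mandatory; every draw derives from it
    n_lakes: int = 28
    n_transects_per_lake: int = 3
    years: tuple[int, ...] = (2010, 2013, 2016)
    species_pool_size: int = 75
    # niche distribution
    optimum_mean: float = -2.0
    optimum_sd: float = 1.2
    tolerance_mean: float = 1.0
    tolerance_sd: float = 0.3
    max_presence_prob_range: tuple[float, float] = (0.2, 0.9)
    # per-lake access to the pool
    lake_access_prob: float = 0.5
    affinity_range: tuple[float, float] = (0.3, 1.0)
    # environment
    seasonal_amplitude: float = 0.25  # fraction of the annual mean
    noise_sd: float = 0.08  # fraction of the annual mean
    missing_month_prob: float = 0.1
    sparse_year_prob: float = 0.15  # chance a lake-year is poorly monitored
    sparse_missing_prob: float = 0.5  # missing-month prob in such years
    below_detection_quantile: float = 0.1  # of the variable's range
    # injected linear drifts per year (zero = stationary system)
    optimum_drift: float = 0.0  # m/yr, positive = shallower
    pool_drift: float = 0.0  # species/yr added (>0) or suppressed (<0)
    env_drift: dict[str, float] = field(default_factory=dict)  # units/yr

    def __post_init__(self) -> None:
        for p in (self.lake_access_prob, self.missing_month_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.species_pool_size < 1:
            raise ValueError("species pool must not be empty")


@dataclass
class SyntheticTruth:
    """Closed-form expectations recorded at generation time."""

    expected_alpha: dict[str, dict[float, float]]  # lake -> depth -> E[alpha]
    expected_peak_depth: dict[str, float]  # lake -> argmax midpoint
    trend_signs: dict[str, int]  # measure -> injected sign (+1/-1/0)

    def to_dict(self) -> dict:
        return {
            "expected_alpha": {
                lake: {str(d): v for d, v in prof.items()}
                for lake, prof in self.expected_alpha.items()
            },
            "expected_peak_depth": self.expected_peak_depth,
            "trend_signs": self.trend_signs,
        }


def _draw_pool(cfg: SimulationConfig, rng: np.random.Generator, size: int) -> list[NicheSpec]:
    optima = np.clip(rng.normal(cfg.optimum_mean, cfg.optimum_sd, size), -6.5, -0.1)
    tols = np.maximum(rng.normal(cfg.tolerance_mean, cfg.tolerance_sd, size), 0.2)
    lo, hi = cfg.max_presence_prob_range
    probs = rng.uniform(lo, hi, size)
    return [
        NicheSpec(f"sp{i:03d}", float(optima[i]), float(tols[i]), float(probs[i]))
        for i in range(size)
    ]


def _lake_ids(n: int) -> list[str]:
    return [f"L{i:02d}" for i in range(1, n + 1)]


def generate_lake_system(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, LakeMeta], dict[str, WaterLevelStats], pd.DataFrame, SyntheticTruth]:
    """Generate a full virtual lake system.

    Returns (surveys, lake metadata, water-level stats, monthly samples,
    truth).  Identical configs (same seed) give identical outputs.  All
    lakes pass the filtering gate (deep, natural, dimictic, unregulated)
    and every species is a submerged, species-rank taxon, so the generated
    archive survives `filter_records` untouched apart from campaign-level
    rules the caller configures deliberately.
    """
    rng = np.random.default_rng(config.seed)
    pool = _draw_pool(config, rng, config.species_pool_size)
    lakes = _lake_ids(config.n_lakes)

    # per-lake species affinities
    affinity = {}
    lo, hi = config.affinity_range
    for lake in lakes:
        access = rng.random(len(pool)) < config.lake_access_prob
        aff = np.where(access, rng.uniform(lo, hi, len(pool)), 0.0)
        affinity[lake] = aff

    metas = {}
    wls = {}
    for lake in lakes:
        metas[lake] = LakeMeta(
            lake_id=lake,
            area_ha=float(np.round(rng.uniform(130.0, 8000.0), 1)),
            max_depth_m=float(np.round(rng.uniform(12.0, 190.0), 1)),
            mixing_regime="dimictic",
            natural=True,
            natural_water_level=True,
        )
        mlw = float(np.round(rng.uniform(0.5, 2.0), 2))
        wls[lake] = WaterLevelStats(lake, mhw_m=float(np.round(mlw + rng.uniform(0.2, 1.2), 2)), mlw_m=mlw)

    surveys = _draw_surveys(config, rng, pool, lakes, affinity)
    monthly = _draw_monthly(config, rng, lakes)

    # analytic expectations for the stationary (first-year) system
    expected_alpha: dict[str, dict[float, float]] = {}
    expected_peak: dict[str, float] = {}
    for lake in lakes:
        prof = {
            d: float(sum(a * s.presence_prob(d) for a, s in zip(affinity[lake], pool)))
            for d in MIDPOINTS
        }
        expected_alpha[lake] = prof
        expected_peak[lake] = max(prof, key=prof.get)

    signs = {
        "d_alpha_max": int(np.sign(config.optimum_drift)),
        "total_gamma": int(np.sign(config.pool_drift)),
    }
    signs.update({f"env_{k}": int(np.sign(v)) for k, v in config.env_drift.items()})

    truth = SyntheticTruth(expected_alpha, expected_peak, signs)
    return surveys, metas, wls, monthly, truth


def _draw_surveys(
    config: SimulationConfig,
    rng: np.random.Generator,
    pool: list[NicheSpec],
    lakes: list[str],
    affinity: dict[str, np.ndarray],
) -> pd.DataFrame:
    rows = []
    year0 = min(config.years)
    for year in config.years:
        dt = year - year0
        # niche optima drift (positive drift moves optima toward the surface)
        shift = config.optimum_drift * dt
        # pool drift: grow by unlocking extra species, shrink by suppression
        n_active = int(round(config.species_pool_size + min(config.pool_drift, 0) * dt))
        n_active = max(n_active, 1)
        extra = int(round(max(config.pool_drift, 0) * dt))
        active = list(range(min(n_active, len(pool))))
        for lake in lakes:
            aff = affinity[lake].copy()
            if extra:
                # drifting pool: previously locked-out species gain access
                zero = np.flatnonzero(aff == 0)
                gain = zero[:extra]
                aff[gain] = np.mean(config.affinity_range)
            for t in range(1, config.n_transects_per_lake + 1):
                tid = f"T{t}"
                for label, depth in zip(DEPTH_LABELS, MIDPOINTS):
                    for si in active:
                        s = pool[si]
                        p = aff[si] * NicheSpec(
                            s.species_id,
                            min(s.optimum_depth + shift, -0.1),
                            s.tolerance,
                            s.max_presence_prob,
                        ).presence_prob(depth)
                        if rng.random() < p:
                            rows.append(
                                (
                                    lake,
                                    year,
                                    tid,
                                    label,
                                    s.species_id,
                                    "species",
                                    "submerged",
                                    int(rng.integers(1, 6)),
                                )
                            )
    return pd.DataFrame(
        rows,
        columns=[
            "lake_id",
            "year",
            "transect_id",
            "depth_class",
            "taxon",
            "rank",
            "growth_form",
            "kohler_freq",
        ],
    )


def _draw_monthly(
    config: SimulationConfig, rng: np.random.Generator, lakes: list[str]
) -> pd.DataFrame:
    rows = []
    year0 = min(config.years)
    months = np.arange(1, 13)
    season = np.sin(2 * np.pi * (months - 4) / 12.0)  # peak in summer
    for lake in lakes:
        base = {v: rng.uniform(*ENV_RANGES[v]) for v in ENV_VARIABLES}
        for year in config.years:
            dt = year - year0
            # occasional sparsely monitored lake-years thin the whole campaign,
            # pushing it below the 8-month rule and out of the complete tier
            sparse = rng.random() < config.sparse_year_prob
            p_miss = config.sparse_missing_prob if sparse else config.missing_month_prob
            for var in ENV_VARIABLES:
                lo, hi = ENV_RANGES[var]
                mean = base[var] + config.env_drift.get(var, 0.0) * dt
                amp = config.seasonal_amplitude * max(abs(mean), 0.05 * (hi - lo))
                sd = config.noise_sd * max(abs(mean), 0.05 * (hi - lo))
                det = lo + config.below_detection_quantile * (hi - lo)
                depths = (0.0, -2.0, -4.0, -6.0) if var == "Temp" else (0.0,)
                # a missed sampling month is missed at every depth at once
                present = rng.random(12) >= p_miss
                for depth in depths:
                    # stratified lakes: seasonal swing shrinks with depth
                    damp = 1.0 if var != "Temp" else {0.0: 1.0, -2.0: 0.8, -4.0: 0.45, -6.0: 0.25}[depth]
                    vals = mean + damp * amp * season + rng.normal(0, sd, 12)
                    if var != "pH":
                        vals = np.maximum(vals, 0.0)
                    for m, v, keep in zip(months, vals, present):
                        if not keep:
                            continue
                        below = var in _DETECTION_LIMITED and v < det
                        rows.append((lake, year, int(m), var, depth, float(np.round(v, 4)), bool(below)))
    return pd.DataFrame(
        rows,
        columns=["lake_id", "year", "month", "variable", "measure_depth_m", "value", "below_detection"],
    )


def generate_temporal_series(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Multi-year surveys with injected linear drifts and truth signs.

    Requires at least three survey years (the time-series tier rule).
    Truth records the injected sign per measure: `d_alpha_max` follows the
    niche-optimum drift (positive = peak becomes shallower) and
    `total_gamma` follows the pool drift.
    """
    if len(config.years) < 3:
        raise ValueError("temporal series needs >= 3 survey years")
    surveys, _, _, _, truth = generate_lake_system(config)
    return surveys, truth


def write_system(
    outdir,
    surveys: pd.DataFrame,
    metas: dict[str, LakeMeta],
    wls: dict[str, WaterLevelStats],
    monthly: pd.DataFrame,
    truth: SyntheticTruth,
) -> None:
    """Write the generated system under `outdir` in the canonical schemas."""
    import json
    from pathlib import Path

    from . import io as lio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lio.write_surveys(surveys, outdir / "surveys.csv")
    lio.write_lakes(metas, outdir / "lakes.csv")
    lio.write_waterlevel(wls, outdir / "waterlevel.csv")
    lio.write_monthly(monthly, outdir / "monthly.csv")
    (outdir / "truth.json").write_text(json.dumps(truth.to_dict(), indent=2))
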