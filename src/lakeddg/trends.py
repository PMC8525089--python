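"""Temporal stability and linear trends of the DDG measures.

Stability of a measure over a lake's survey years is summarised by the
invariability coefficient IC = mean / sd, the inverse of the coefficient
of variation.  Trends are ordinary least-squares regressions of a measure
on calendar year, fitted per lake and pooled over all lakes, with the
slope's two-sided p-value mapped to the conventional significance marks
(*** < .001, ** < .01, * < .05, . < .1, ns otherwise).

Sign convention: depths are negative metres, so a positive D_max slope
means the richness peak becomes shallower over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SIGNIFICANCE_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "."))


def significance_class(p: float) -> str:
    for cut, mark in SIGNIFICANCE_LEVELS:
        if p < cut:
            return mark
    return "ns"


@dataclass(frozen=True)
class InvariabilityResult:
    """Stability of one measure in one lake: IC = mean / sd."""

    lake_id: str
    measure: str
    mean: float
    sd: float
    ic: float  # inf when sd == 0 (flagged perfectly stable)

    @property
    def cv(self) -> float:
        return self.sd / self.mean

    @property
    def infinitely_stable(self) -> bool:
        return not math.isfinite(self.ic)


@dataclass(frozen=True)
class TrendResult:
    """Per-lake (or pooled) linear trend of one measure over years."""

    lake_id: str  # "ALL" for the pooled fit
    measure: str
    slope: float
    p: float
    sign: str  # "+" or "-"
    significance: str  # "***", "**", "*", ".", "ns"


def invariability(series: pd.Series | np.ndarray, lake_id: str, measure: str) -> InvariabilityResult:
    """IC of a measure over at least three years (sample sd).

    Raises on a non-positive mean (IC is meaningless); a zero sd returns
    an infinite IC flagged as perfectly stable.
    """
    x = np.asarray(series, float)
    if len(x) < 3:
        raise ValueError(f"need >= 3 years for IC, got {len(x)}")
    mean = float(x.mean())
    if mean <= 0:
        raise ValueError(f"IC undefined for non-positive mean ({mean})")
    sd = float(x.std(ddof=1))
    ic = mean / sd if sd > 0 else float("inf")
    return InvariabilityResult(lake_id, measure, mean, sd, ic)


def _ols_trend(years: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(years, values)
    p = res.pvalue if np.isfinite(res.pvalue) else 0.0
    return float(res.slope), float(p)


def trend_table(
    measures: pd.DataFrame,
    measure_cols: list[str],
    min_years: int = 3,
) -> tuple[list[TrendResult], list[str]]:
    """Linear year-trends per lake and pooled over all lakes.

    `measures` holds one row per campaign with `lake_id`, `year`, and the
    measure columns.  Lakes with fewer than `min_years` distinct survey
    years are skipped and reported in the returned log.  Calendar year is
    used as the regressor, so uneven sampling intervals are honoured.
    """
    results: list[TrendResult] = []
    skipped: list[str] = []
    skipped_lakes: set[str] = set()
    lakes = sorted(measures["lake_id"].unique())
    for lake in lakes:
        sub = measures[measures["lake_id"] == lake]
        if sub["year"].nunique() < min_years:
            skipped.append(f"{lake}: only {sub['year'].nunique()} survey years")
            skipped_lakes.add(lake)
            continue
        for col in measure_cols:
            vals = sub[["year", col]].dropna()
            if vals[col].nunique() < 2 or len(vals) < min_years:
                slope, p = 0.0, 1.0
            else:
                slope, p = _ols_trend(vals["year"].to_numpy(float), vals[col].to_numpy(float))
            results.append(
                TrendResult(lake, col, slope, p, "+" if slope >= 0 else "-", significance_class(p))
            )
    pooled = measures[~measures["lake_id"].isin(skipped_lakes)]
    for col in measure_cols:
        vals = pooled[["year", col]].dropna()
        if len(vals) >= min_years and vals[col].nunique() >= 2:
            slope, p = _ols_trend(vals["year"].to_numpy(float), vals[col].to_numpy(float))
        else:
            slope, p = 0.0, 1.0
        results.append(
            TrendResult("ALL", col, slope, p, "+" if slope >= 0 else "-", significance_class(p))
        )
    return results, skipped


def trend_frame(results: list[TrendResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lake_id": [r.lake_id for r in results],
            "measure": [r.measure for r in results],
            "slope": [r.slope for r in results],
            "p": [r.p for r in results],
            "sign": [r.sign for r in results],
            "significance": [r.significance for r in results],
        }
    )


def trend_matrix(results: list[TrendResult]) -> pd.DataFrame:
    """Lakes x measures table of sign + significance marks.

    Cells read like "+**" (significant positive trend) or "-" (negative,
    not significant), the layout used for reporting per-lake trends.
    """
    df = trend_frame(results)
    df["cell"] = df["sign"] + df["significance"].where(df["significance"] != "ns", "")
    return df.pivot(index="lake_id", columns="measure", values="cell")
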