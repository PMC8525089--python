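"""Depth-diversity-gradient (DDG) peak measures and pattern classes.

A DDG curve is richness against the four depth midpoints.  Its peak is
summarised by D_max (depth of the maximum, metres, negative downward) and
R_max (the maximum richness).  Ties between depth classes are resolved by
averaging the tied midpoints, so D_max can fall between classes.

For alpha richness the peak is found per transect and then averaged across
the campaign's transects; for beta and gamma the peak is taken on the
campaign-level profile directly.

Curves are classified into four pattern types by D_max:

* decreasing       D_max > -1 m
* shallow_hump     -2 m <  D_max <= -1 m
* deep_hump        -4 m <  D_max <= -2 m
* increasing       D_max <= -4 m

Boundary values (only reachable through tie-averages) go to the deeper
class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .depths import MIDPOINTS
from .io import add_midpoints

PATTERN_TYPES = ("decreasing", "shallow_hump", "deep_hump", "increasing")

COMPONENTS = ("alpha", "beta", "gamma")


@dataclass(frozen=True)
class DDGMeasures:
    """Peak measures of one richness component of one campaign."""

    lake_id: str
    year: int
    component: str
    d_max: float
    r_max: float
    pattern: str
    n_empty_transects: int = 0  # alpha only: all-zero transects excluded


def transect_peak(counts: dict[float, float]) -> tuple[float, float]:
    """Peak of one transect's depth-count curve.

    Returns (peak_depth, peak_count).  When several depth classes tie at the
    maximum count, the peak depth is the arithmetic mean of the tied
    midpoints.

    Raises
    ------
    ValueError
        If the counts do not cover the four canonical midpoints, or are all
        zero (the argmax is undefined; such transects are excluded upstream).
    """
    if set(counts) != set(MIDPOINTS):
        raise ValueError(f"counts must cover the four midpoints, got {sorted(counts)}")
    values = np.array([counts[d] for d in MIDPOINTS], dtype=float)
    peak = values.max()
    if peak <= 0:
        raise ValueError("all-zero transect: peak depth undefined")
    tied = [d for d, v in zip(MIDPOINTS, values) if v == peak]
    return float(np.mean(tied)), float(peak)


def classify_pattern(d_max: float) -> str:
    """Map a peak depth to its DDG pattern type (boundaries to deeper class)."""
    if not (MIDPOINTS[-1] <= d_max <= MIDPOINTS[0]):
        raise ValueError(f"D_max {d_max} outside [{MIDPOINTS[-1]}, {MIDPOINTS[0]}]")
    if d_max > -1.0:
        return "decreasing"
    if d_max > -2.0:
        return "shallow_hump"
    if d_max > -4.0:
        return "deep_hump"
    return "increasing"


def ddg_alpha_measures(records: pd.DataFrame, lake_id: str, year: int) -> DDGMeasures:
    """Alpha peak: per-transect peaks averaged across transects.

    D_(alpha,max) is the mean of the transect peak depths and R_(alpha,max)
    the mean of the transect peak counts.  Transects with no species at any
    depth are excluded from the averages (their count is reported).
    """
    sel = add_midpoints(
        records[(records["lake_id"] == lake_id) & (records["year"] == int(year))]
    )
    if sel.empty:
        raise ValueError(f"no records for campaign ({lake_id}, {year})")
    counts = (
        sel.groupby(["transect_id", "depth_m"])["taxon"].nunique().unstack(fill_value=0)
    )
    counts = counts.reindex(columns=list(MIDPOINTS), fill_value=0)
    peaks = []
    n_empty = 0
    for _, row in counts.iterrows():
        if row.max() <= 0:
            n_empty += 1
            continue
        peaks.append(transect_peak(row.to_dict()))
    if not peaks:
        raise ValueError(f"campaign ({lake_id}, {year}): no non-empty transect")
    d = float(np.mean([p[0] for p in peaks]))
    r = float(np.mean([p[1] for p in peaks]))
    return DDGMeasures(lake_id, int(year), "alpha", d, r, classify_pattern(d), n_empty)


def ddg_profile_measures(
    profile: dict[float, float], component: str, lake_id: str = "", year: int = 0
) -> DDGMeasures:
    """Peak of a campaign-level (beta or gamma) profile, same tie rule."""
    d, r = transect_peak(profile)
    return DDGMeasures(lake_id, int(year), component, d, r, classify_pattern(d))


def all_measures(records: pd.DataFrame) -> list[DDGMeasures]:
    """DDG measures for every campaign and every richness component."""
    from .partition import all_profiles

    out: list[DDGMeasures] = []
    for prof in all_profiles(records):
        out.append(ddg_alpha_measures(records, prof.lake_id, prof.year))
        for comp, profile in (("beta", prof.beta), ("gamma", prof.gamma)):
            out.append(
                ddg_profile_measures(
                    {d: float(v) for d, v in profile.items()},
                    comp,
                    prof.lake_id,
                    prof.year,
                )
            )
    return out


def measures_frame(measures: list[DDGMeasures]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lake_id": [m.lake_id for m in measures],
            "year": [m.year for m in measures],
            "component": [m.component for m in measures],
            "d_max": [m.d_max for m in measures],
            "r_max": [m.r_max for m in measures],
            "pattern": [m.pattern for m in measures],
        }
    )


def pattern_frequencies(measures: list[DDGMeasures], component: str) -> dict[str, float]:
    """Percentage of campaigns in each pattern type, for one component.

    Shares are reported in percent and sum to 100 up to rounding.
    """
    pats = [m.pattern for m in measures if m.component == component]
    if not pats:
        raise ValueError(f"no measures for component {component!r}")
    n = len(pats)
    return {p: 100.0 * pats.count(p) / n for p in PATTERN_TYPES}


def pattern_table(measures: list[DDGMeasures]) -> pd.DataFrame:
    """Contingency table of pattern-type counts per richness component."""
    df = measures_frame(measures)
    tab = (
        df.groupby(["component", "pattern"]).size().unstack(fill_value=0)
    )
    return tab.reindex(index=list(COMPONENTS), columns=list(PATTERN_TYPES), fill_value=0)
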