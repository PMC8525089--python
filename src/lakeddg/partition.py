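"""Additive alpha/beta/gamma richness partitioning along the depth gradient.

For one field campaign (one lake, one year):

* alpha richness at depth d — the number of distinct species per transect in
  depth class d, averaged over the campaign's transects.  Every transect
  contributes a count to every one of the four depth classes; a transect
  with no record in a class contributes 0 (the survey spans shoreline to
  the lowest occurrence, so absence is an observed zero).
* gamma richness at depth d — the number of distinct species over the union
  of all transects in class d.
* beta richness at depth d — gamma(d) − alpha(d), the additive turnover
  component; non-negative by construction.
* total gamma — distinct species across all transects and depths
  (depth-independent).

Richness is presence/absence: the Kohler frequency is ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .depths import MIDPOINTS
from .io import add_midpoints


@dataclass(frozen=True)
class RichnessProfile:
    """Alpha/beta/gamma richness of one campaign at the four depth midpoints."""

    lake_id: str
    year: int
    alpha: dict[float, float]
    gamma: dict[float, int]
    beta: dict[float, float]
    total_gamma: int
    n_transects: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lake_id": self.lake_id,
                "year": self.year,
                "depth_m": list(MIDPOINTS),
                "alpha": [self.alpha[d] for d in MIDPOINTS],
                "beta": [self.beta[d] for d in MIDPOINTS],
                "gamma": [self.gamma[d] for d in MIDPOINTS],
            }
        )


def _campaign(records: pd.DataFrame, lake_id: str, year: int) -> pd.DataFrame:
    sel = records[(records["lake_id"] == lake_id) & (records["year"] == int(year))]
    if sel.empty:
        raise ValueError(f"no records for campaign ({lake_id}, {year})")
    return add_midpoints(sel)


def alpha_profile(records: pd.DataFrame, lake_id: str, year: int) -> dict[float, float]:
    """Mean per-transect species count at each depth midpoint."""
    camp = _campaign(records, lake_id, year)
    transects = camp["transect_id"].unique()
    counts = (
        camp.groupby(["transect_id", "depth_m"])["taxon"].nunique().unstack(fill_value=0)
    )
    counts = counts.reindex(index=transects, columns=list(MIDPOINTS), fill_value=0)
    return {d: float(counts[d].mean()) for d in MIDPOINTS}


def gamma_profile(records: pd.DataFrame, lake_id: str, year: int) -> dict[float, int]:
    """Union species count over transects at each depth midpoint."""
    camp = _campaign(records, lake_id, year)
    counts = camp.groupby("depth_m")["taxon"].nunique()
    return {d: int(counts.get(d, 0)) for d in MIDPOINTS}


def beta_profile(
    alpha: dict[float, float], gamma: dict[float, int]
) -> dict[float, float]:
    """Additive beta: gamma minus alpha, pointwise along depth."""
    if set(alpha) != set(gamma):
        raise ValueError("alpha and gamma profiles cover different depths")
    beta = {d: gamma[d] - alpha[d] for d in alpha}
    neg = {d: b for d, b in beta.items() if b < -1e-9}
    if neg:
        raise ValueError(f"negative beta at {neg}: profiles from different campaigns?")
    return {d: max(b, 0.0) for d, b in beta.items()}


def total_gamma(records: pd.DataFrame, lake_id: str, year: int) -> int:
    """Distinct species across all transects and depths of a campaign."""
    camp = _campaign(records, lake_id, year)
    n = int(camp["taxon"].nunique())
    if n == 0:
        warnings.warn(f"campaign ({lake_id}, {year}) has no species", stacklevel=2)
    return n


def richness_profile(records: pd.DataFrame, lake_id: str, year: int) -> RichnessProfile:
    """Full additive partition for one campaign."""
    a = alpha_profile(records, lake_id, year)
    g = gamma_profile(records, lake_id, year)
    camp = _campaign(records, lake_id, year)
    return RichnessProfile(
        lake_id=lake_id,
        year=int(year),
        alpha=a,
        gamma=g,
        beta=beta_profile(a, g),
        total_gamma=total_gamma(records, lake_id, year),
        n_transects=int(camp["transect_id"].nunique()),
    )


def all_profiles(records: pd.DataFrame) -> list[RichnessProfile]:
    """Partition every campaign present in `records`."""
    keys = records[["lake_id", "year"]].drop_duplicates().sort_values(["lake_id", "year"])
    return [richness_profile(records, lid, yr) for lid, yr in keys.itertuples(index=False)]


def profiles_frame(profiles: list[RichnessProfile]) -> pd.DataFrame:
    """Long table: one row per campaign x depth with alpha/beta/gamma."""
    if not profiles:
        return pd.DataFrame(
            columns=["lake_id", "year", "depth_m", "alpha", "beta", "gamma"]
        )
    return pd.concat([p.as_frame() for p in profiles], ignore_index=True)


def summary_frame(profiles: list[RichnessProfile]) -> pd.DataFrame:
    """Per-campaign summary with total gamma and transect count."""
    return pd.DataFrame(
        {
            "lake_id": [p.lake_id for p in profiles],
            "year": [p.year for p in profiles],
            "total_gamma": [p.total_gamma for p in profiles],
            "n_transects": [p.n_transects for p in profiles],
        }
    )


def mean_profile(profiles: list[RichnessProfile], component: str) -> pd.DataFrame:
    """Mean and SD of a richness component per depth, across campaigns."""
    long = profiles_frame(profiles)
    g = long.groupby("depth_m")[component]
    return pd.DataFrame(
        {"depth_m": list(g.mean().index), "mean": g.mean().values, "sd": g.std(ddof=1).values}
    )
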