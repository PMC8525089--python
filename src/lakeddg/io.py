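"""Readers, writers, and filtering rules for the survey data model.

Tables are exchanged as UTF-8 CSV and held in memory as pandas DataFrames
with fixed column sets:

surveys.csv     lake_id, year, transect_id, depth_class, taxon, rank,
                growth_form, kohler_freq
lakes.csv       lake_id, area_ha, max_depth_m, mixing_regime, natural,
                natural_water_level
waterlevel.csv  lake_id, mhw_m, mlw_m
monthly.csv     lake_id, year, month, variable, measure_depth_m, value,
                below_detection

One survey row is one taxon observation in one depth class of one transect
of one field campaign (a lake mapped in one year).  The Kohler frequency
(five-step ordinal abundance) is carried through but ignored by all
richness computations, which are presence/absence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .depths import DEPTH_LABELS, depth_midpoint

SURVEY_COLUMNS = [
    "lake_id",
    "year",
    "transect_id",
    "depth_class",
    "taxon",
    "rank",
    "growth_form",
    "kohler_freq",
]

LAKE_COLUMNS = [
    "lake_id",
    "area_ha",
    "max_depth_m",
    "mixing_regime",
    "natural",
    "natural_water_level",
]

MONTHLY_COLUMNS = [
    "lake_id",
    "year",
    "month",
    "variable",
    "measure_depth_m",
    "value",
    "below_detection",
]

#: The 12 physiochemical variables measured monthly at the deepest point.
ENV_VARIABLES = (
    "Chl",
    "Cond",
    "N_tot",
    "NH4",
    "NO3",
    "O2diss",
    "P_tot",
    "pH",
    "SiO2",
    "Temp",
    "Transp",
    "SAC",
)

RANKS = ("species", "genus", "higher")
GROWTH_FORMS = ("submerged", "emergent", "floating_leaved")

# Label aliases seen in raw exports, normalised on ingestion.
_DEPTH_ALIASES = {
    "0-1": "0-1",
    "0–1": "0-1",
    "1-2": "1-2",
    "1–2": "1-2",
    "2-4": "2-4",
    "2–4": "2-4",
    ">4": ">4",
    ">-4": ">4",
}


@dataclass(frozen=True)
class LakeMeta:
    """Static lake descriptors used by the selection gate."""

    lake_id: str
    area_ha: float
    max_depth_m: float
    mixing_regime: str  # "dimictic" or "other"
    natural: bool
    natural_water_level: bool

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError(f"lake {self.lake_id}: area must be > 0")
        if self.max_depth_m <= 0:
            raise ValueError(f"lake {self.lake_id}: max depth must be > 0")


@dataclass(frozen=True)
class WaterLevelStats:
    """Gauge summary per lake; WLF = MHW - MLW."""

    lake_id: str
    mhw_m: float
    mlw_m: float

    def __post_init__(self) -> None:
        if self.mhw_m < self.mlw_m:
            raise ValueError(
                f"lake {self.lake_id}: MHW ({self.mhw_m}) < MLW ({self.mlw_m})"
            )

    @property
    def wlf_m(self) -> float:
        return self.mhw_m - self.mlw_m


def read_surveys(path: str | Path) -> pd.DataFrame:
    """Read a survey CSV, normalising depth labels and validating rows.

    Raises
    ------
    ValueError
        On an unknown depth label or a Kohler frequency outside 1..5,
        naming the offending row.
    """
    df = pd.read_csv(path, dtype={"lake_id": str, "transect_id": str})
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing survey columns {sorted(missing)}")
    df = df[SURVEY_COLUMNS].copy()
    if df.empty:
        return df

    labels = df["depth_class"].astype(str).str.strip()
    bad = ~labels.isin(_DEPTH_ALIASES)
    if bad.any():
        i = int(bad.idxmax())
        raise ValueError(
            f"{path}: row {i}: unknown depth class label {labels.loc[i]!r}"
        )
    df["depth_class"] = labels.map(_DEPTH_ALIASES)

    kf = pd.to_numeric(df["kohler_freq"], errors="coerce")
    bad = ~kf.isin([1, 2, 3, 4, 5])
    if bad.any():
        i = int(bad.idxmax())
        raise ValueError(
            f"{path}: row {i}: kohler_freq {df['kohler_freq'].loc[i]!r} not in 1..5"
        )
    df["kohler_freq"] = kf.astype(int)
    df["year"] = df["year"].astype(int)
    return df


def write_surveys(df: pd.DataFrame, path: str | Path) -> None:
    df[SURVEY_COLUMNS].to_csv(path, index=False)


def read_lakes(path: str | Path) -> dict[str, LakeMeta]:
    df = pd.read_csv(path, dtype={"lake_id": str})
    metas = {}
    for row in df.itertuples(index=False):
        metas[row.lake_id] = LakeMeta(
            lake_id=row.lake_id,
            area_ha=float(row.area_ha),
            max_depth_m=float(row.max_depth_m),
            mixing_regime=str(row.mixing_regime),
            natural=bool(row.natural),
            natural_water_level=bool(row.natural_water_level),
        )
    return metas


def write_lakes(metas: dict[str, LakeMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "lake_id": m.lake_id,
                "area_ha": m.area_ha,
                "max_depth_m": m.max_depth_m,
                "mixing_regime": m.mixing_regime,
                "natural": m.natural,
                "natural_water_level": m.natural_water_level,
            }
            for m in metas.values()
        ]
    ).to_csv(path, index=False)


def read_waterlevel(path: str | Path) -> dict[str, WaterLevelStats]:
    df = pd.read_csv(path, dtype={"lake_id": str})
    return {
        row.lake_id: WaterLevelStats(row.lake_id, float(row.mhw_m), float(row.mlw_m))
        for row in df.itertuples(index=False)
    }


def write_waterlevel(stats: dict[str, WaterLevelStats], path: str | Path) -> None:
    pd.DataFrame(
        [{"lake_id": s.lake_id, "mhw_m": s.mhw_m, "mlw_m": s.mlw_m} for s in stats.values()]
    ).to_csv(path, index=False)


def read_monthly(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"lake_id": str})
    missing = set(MONTHLY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing monthly columns {sorted(missing)}")
    df = df[MONTHLY_COLUMNS].copy()
    if not df.empty:
        dup = df.duplicated(
            subset=["lake_id", "year", "month", "variable", "measure_depth_m"]
        )
        if dup.any():
            i = int(dup.idxmax())
            raise ValueError(f"{path}: row {i}: duplicate monthly sample key")
        df["below_detection"] = df["below_detection"].astype(bool)
    return df


def write_monthly(df: pd.DataFrame, path: str | Path) -> None:
    df[MONTHLY_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Record/lake filtering
# ---------------------------------------------------------------------------

#: Exclusion-rule identifiers, in application order.
RULE_LAKE_GATE = "lake_gate"  # not deep/natural/dimictic/unregulated
RULE_NO_REPEAT = "no_repeat_mapping"  # lake mapped in < 2 distinct years
RULE_GROWTH_FORM = "growth_form"  # emergent / floating-leaved record
RULE_NOT_SPECIES = "not_species_rank"  # record not determined to species
RULE_ONE_TRANSECT = "single_transect_campaign"  # campaign with one transect


@dataclass
class ExclusionLog:
    """Counts of removed rows / campaigns / lakes per filtering rule."""

    rows_removed: dict[str, int] = field(default_factory=dict)
    campaigns_removed: dict[str, int] = field(default_factory=dict)
    lakes_removed: dict[str, int] = field(default_factory=dict)

    def add_rows(self, rule: str, n: int) -> None:
        if n:
            self.rows_removed[rule] = self.rows_removed.get(rule, 0) + n

    def add_campaigns(self, rule: str, n: int) -> None:
        if n:
            self.campaigns_removed[rule] = self.campaigns_removed.get(rule, 0) + n

    def add_lakes(self, rule: str, n: int) -> None:
        if n:
            self.lakes_removed[rule] = self.lakes_removed.get(rule, 0) + n

    @property
    def total_rows_removed(self) -> int:
        return sum(self.rows_removed.values())

    def to_json_lines(self) -> str:
        lines = []
        for level, d in (
            ("rows", self.rows_removed),
            ("campaigns", self.campaigns_removed),
            ("lakes", self.lakes_removed),
        ):
            for rule, n in d.items():
                lines.append(json.dumps({"level": level, "rule": rule, "removed": n}))
        return "\n".join(lines) + ("\n" if lines else "")


def lake_passes_gate(meta: LakeMeta) -> bool:
    """Deep (>10 m max depth), natural, dimictic, unregulated water level."""
    return (
        meta.max_depth_m > 10
        and meta.natural
        and meta.mixing_regime == "dimictic"
        and meta.natural_water_level
    )


def filter_records(
    records: pd.DataFrame, metas: dict[str, LakeMeta]
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the lake gate and record/campaign exclusion rules.

    Removes, in order: (a) all records of lakes failing the gate
    (shallow, artificial, non-dimictic, or regulated); (b) records of
    emergent or floating-leaved growth forms; (c) records not determined to
    species rank; then iterates to a fixed point the campaign-level rules:
    campaigns surveyed along a single transect, and lakes left with fewer
    than two distinct survey years (no repeat mapping).

    Returns the filtered records and an :class:`ExclusionLog`.  Idempotent:
    a second application removes nothing.

    Raises
    ------
    KeyError
        If a surveyed lake has no metadata entry.
    """
    log = ExclusionLog()
    df = records.copy()

    unknown = set(df["lake_id"].unique()) - set(metas)
    if unknown:
        raise KeyError(f"no metadata for lake(s): {sorted(unknown)}")

    # (a) lake gate
    ok_lakes = {lid for lid, m in metas.items() if lake_passes_gate(m)}
    mask = df["lake_id"].isin(ok_lakes)
    log.add_rows(RULE_LAKE_GATE, int((~mask).sum()))
    log.add_lakes(RULE_LAKE_GATE, df.loc[~mask, "lake_id"].nunique())
    df = df[mask]

    # (b) growth form: only submerged forms are retained
    mask = df["growth_form"] == "submerged"
    log.add_rows(RULE_GROWTH_FORM, int((~mask).sum()))
    df = df[mask]

    # (c) taxonomic rank: species-level determinations only
    mask = df["rank"] == "species"
    log.add_rows(RULE_NOT_SPECIES, int((~mask).sum()))
    df = df[mask]

    # campaign-level rules to fixed point
    while True:
        n_tr = df.groupby(["lake_id", "year"])["transect_id"].nunique()
        single = n_tr[n_tr < 2]
        if len(single):
            key = pd.MultiIndex.from_frame(df[["lake_id", "year"]])
            mask = key.isin(single.index)
            log.add_campaigns(RULE_ONE_TRANSECT, len(single))
            log.add_rows(RULE_ONE_TRANSECT, int(mask.sum()))
            df = df[~mask]
            continue
        n_years = df.groupby("lake_id")["year"].nunique()
        once = n_years[n_years < 2]
        if len(once):
            mask = df["lake_id"].isin(once.index)
            log.add_lakes(RULE_NO_REPEAT, len(once))
            log.add_campaigns(
                RULE_NO_REPEAT,
                int(df[mask].groupby(["lake_id", "year"]).ngroups),
            )
            log.add_rows(RULE_NO_REPEAT, int(mask.sum()))
            df = df[~mask]
            continue
        break

    return df.reset_index(drop=True), log


def dataset_tiers(
    records: pd.DataFrame, env_complete: set[tuple[str, int]] | None = None
) -> dict[str, set[tuple[str, int]]]:
    """Assign field campaigns to the three analysis tiers.

    ``biodiversity`` holds every campaign surviving the filters;
    ``environment_biodiversity`` those with complete annual abiotic data
    (as given by `env_complete`); ``time_series`` those of lakes mapped in
    at least three distinct years.
    """
    campaigns = {
        (lid, int(yr)) for lid, yr in records[["lake_id", "year"]].drop_duplicates().itertuples(index=False)
    }
    years_per_lake: dict[str, set[int]] = {}
    for lid, yr in campaigns:
        years_per_lake.setdefault(lid, set()).add(yr)
    ts_lakes = {lid for lid, yrs in years_per_lake.items() if len(yrs) >= 3}
    tiers = {
        "biodiversity": campaigns,
        "environment_biodiversity": campaigns & (env_complete or set()),
        "time_series": {(lid, yr) for lid, yr in campaigns if lid in ts_lakes},
    }
    return tiers


def add_midpoints(records: pd.DataFrame) -> pd.DataFrame:
    """Append a `depth_m` midpoint column derived from `depth_class`."""
    out = records.copy()
    out["depth_m"] = out["depth_class"].map(depth_midpoint)
    return out
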