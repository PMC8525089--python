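"""Per-campaign environmental records and their PCA reduction.

The abiotic side of the analysis: annual means of the 12 monthly
physiochemical variables (surface measurements; temperature also at -2,
-4, -6 m for the stratification proxy Tempsd), water-level fluctuation
(WLF = mean high water - mean low water), and lake area.  Annual means are
only formed from campaigns with at least eight monthly values; values below
the detection limit count as zero.  Before multivariate analysis the
variables are log-transformed (pH exempt, being a log scale already) and
standardized; a PCA reduces them to the minimal set of leading axes
holding > 80% of the variance, each axis named after the variables it
carries (> 40% of a variable's variance on that axis).

The representativeness of the complete-data subset is checked with a
PERMANOVA (pseudo-F from label permutations on Euclidean distances).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from skbio.stats.distance import DistanceMatrix, permanova

from .io import ENV_VARIABLES, LakeMeta, WaterLevelStats

#: Depths (m) of the temperature series entering Tempsd.
TEMP_DEPTHS = (0.0, -2.0, -4.0, -6.0)

#: Variables entering the PCA driver analysis (Table-style annual features).
DRIVER_VARIABLES = tuple(ENV_VARIABLES) + ("Tempsd", "Area", "WLF")

MIN_MONTHS = 8


def annual_means(
    monthly: pd.DataFrame, lake_id: str, year: int
) -> dict[str, float]:
    """Annual mean of each physiochemical variable for one campaign.

    Only surface samples enter (temperature uses the 0 m series here);
    below-detection values are counted as zero; a variable with fewer than
    eight monthly values in the year is reported as missing (NaN).
    """
    sel = monthly[(monthly["lake_id"] == lake_id) & (monthly["year"] == int(year))]
    out: dict[str, float] = {}
    for var in ENV_VARIABLES:
        vs = sel[(sel["variable"] == var) & (sel["measure_depth_m"] == 0.0)]
        vals = np.where(vs["below_detection"].to_numpy(bool), 0.0, vs["value"].to_numpy(float))
        out[var] = float(np.mean(vals)) if len(vals) >= MIN_MONTHS else np.nan
    return out


def tempsd(monthly: pd.DataFrame, lake_id: str, year: int) -> float:
    """Stratification proxy: SD of temperature across 0/-2/-4/-6 m.

    Computed per month across the four depth series, then averaged over the
    months of the year with all four depths present.  Missing if any depth
    series is entirely absent or fewer than eight months are complete.
    """
    sel = monthly[
        (monthly["lake_id"] == lake_id)
        & (monthly["year"] == int(year))
        & (monthly["variable"] == "Temp")
        & (monthly["measure_depth_m"].isin(TEMP_DEPTHS))
    ]
    wide = sel.pivot_table(index="month", columns="measure_depth_m", values="value")
    if wide.empty or wide.shape[1] < len(TEMP_DEPTHS):
        return float("nan")
    complete = wide.dropna()
    if len(complete) < MIN_MONTHS:
        return float("nan")
    return float(complete.std(axis=1, ddof=1).mean())


def wlf(stats: WaterLevelStats) -> float:
    """Water-level fluctuation: mean high water minus mean low water (m)."""
    return stats.wlf_m


def wlf_from_series(levels: pd.DataFrame) -> float:
    """WLF from a raw gauge series with columns (year, level_m).

    MHW is the mean of the annual maxima and MLW the mean of the annual
    minima, the standard hydrological summary of a gauge record.
    """
    by_year = levels.groupby("year")["level_m"]
    mhw = float(by_year.max().mean())
    mlw = float(by_year.min().mean())
    if mhw < mlw:
        raise ValueError("corrupt gauge series: MHW < MLW")
    return mhw - mlw


def build_env_records(
    monthly: pd.DataFrame,
    metas: dict[str, LakeMeta],
    waterlevels: dict[str, WaterLevelStats],
    campaigns: list[tuple[str, int]],
) -> pd.DataFrame:
    """Environmental record per campaign: annual means + Tempsd + Area + WLF.

    Rows with any missing driver variable are kept (NaN) so the caller can
    form the complete-data tier by dropping them.
    """
    rows = []
    for lake_id, year in campaigns:
        rec: dict[str, object] = {"lake_id": lake_id, "year": int(year)}
        rec.update(annual_means(monthly, lake_id, year))
        rec["Tempsd"] = tempsd(monthly, lake_id, year)
        rec["Area"] = metas[lake_id].area_ha if lake_id in metas else np.nan
        rec["WLF"] = waterlevels[lake_id].wlf_m if lake_id in waterlevels else np.nan
        rows.append(rec)
    return pd.DataFrame(rows, columns=["lake_id", "year", *DRIVER_VARIABLES])


def log_transform(table: pd.DataFrame, exempt: tuple[str, ...] = ("pH",)) -> pd.DataFrame:
    """Natural-log transform each numeric column, offsetting zero-valued ones.

    Columns containing zeros are shifted by half their smallest positive
    observed value before the log; columns without zeros are logged as-is.
    `exempt` columns (pH, already a log scale) pass through unchanged.

    Raises
    ------
    ValueError
        On negative input, naming the column.
    """
    out = table.copy()
    for col in out.columns:
        if col in exempt or not pd.api.types.is_numeric_dtype(out[col]):
            continue
        x = out[col].to_numpy(float)
        finite = x[np.isfinite(x)]
        if (finite < 0).any():
            raise ValueError(f"column {col!r} has negative values; cannot log")
        if (finite == 0).any():
            positive = finite[finite > 0]
            if len(positive) == 0:
                raise ValueError(f"column {col!r} is all zeros; cannot log")
            c = positive.min() / 2.0
        else:
            c = 0.0
        out[col] = np.log(x + c)
    return out


@dataclass(frozen=True)
class PCAResult:
    """Retained leading axes of the standardized driver PCA."""

    loadings: pd.DataFrame  # variables x all axes (orthonormal columns)
    explained: np.ndarray  # explained-variance fractions, all axes
    n_retained: int  # minimal prefix with cumulative variance > 0.80
    axis_names: list[list[str]]  # contributing variables per retained axis
    scores: pd.DataFrame  # observations x retained axes
    mean: np.ndarray
    scale: np.ndarray


def pca_drivers(
    records: pd.DataFrame,
    variance_target: float = 0.80,
    naming_threshold: float = 0.40,
) -> PCAResult:
    """PCA of the (log-transformed) driver table on the correlation scale.

    Columns are standardized to unit variance (the variables' units are
    incommensurable), so the PCA is on the correlation matrix.  The minimal
    prefix of axes whose cumulative explained variance exceeds
    `variance_target` is retained.  Each retained axis is named by every
    variable whose variance is carried to more than `naming_threshold` by
    that axis — i.e. squared variable-axis correlation
    (loading^2 x eigenvalue) above the threshold.  Axes are oriented so
    their largest-magnitude loading is positive.

    Raises
    ------
    ValueError
        On fewer than five complete rows, or a constant column (named).
    """
    numeric = records.select_dtypes("number").drop(columns=["year"], errors="ignore")
    data = numeric.dropna()
    if len(data) < 5:
        raise ValueError(f"need >= 5 complete records for PCA, got {len(data)}")
    for col in data.columns:
        if data[col].nunique() < 2:
            raise ValueError(f"variable {col!r} is constant; drop it before PCA")

    X = data.to_numpy(float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    Z = (X - mean) / scale

    pca = PCA()
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T  # variables x axes, orthonormal columns
    explained = pca.explained_variance_ratio_

    # Sign convention: largest-magnitude loading positive per axis
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1

    cum = np.cumsum(explained)
    n_retained = int(np.searchsorted(cum, variance_target) + 1)
    n_retained = min(n_retained, loadings.shape[1])

    eigvals = pca.explained_variance_
    names = []
    for k in range(n_retained):
        share = loadings[:, k] ** 2 * eigvals[k] / np.var(Z, axis=0, ddof=1)
        names.append([v for v, s in zip(data.columns, share) if s > naming_threshold])

    axis_labels = [f"PC{k + 1}" for k in range(loadings.shape[1])]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=data.columns, columns=axis_labels),
        explained=explained,
        n_retained=n_retained,
        axis_names=names,
        scores=pd.DataFrame(
            scores[:, :n_retained], index=data.index, columns=axis_labels[:n_retained]
        ),
        mean=mean,
        scale=scale,
    )


def representativeness_check(
    subset: pd.DataFrame,
    full: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """PERMANOVA comparing the subset's metrics against the remainder.

    Standardizes the pooled metric columns, computes Euclidean distances,
    and tests subset-vs-rest membership with `n_perm` label permutations.
    Returns (pseudo-F, p).  A non-significant p (> .05) supports treating
    the subset as representative of the full table.

    Raises
    ------
    ValueError
        If either group has fewer than two rows or columns differ.
    """
    if list(subset.columns) != list(full.columns):
        raise ValueError("subset and full tables must share the same metric columns")
    rest = full
    if len(subset) < 2 or len(rest) < 2:
        raise ValueError("each group needs at least two rows")
    pooled = pd.concat([subset, rest], ignore_index=True).to_numpy(float)
    z = (pooled - pooled.mean(axis=0)) / pooled.std(axis=0, ddof=1)
    dm = DistanceMatrix(squareform(pdist(z)), ids=[str(i) for i in range(len(z))])
    grouping = ["subset"] * len(subset) + ["rest"] * len(rest)
    np.random.seed(seed % (2**32))  # skbio permutes via the global RNG
    res = permanova(dm, grouping, permutations=n_perm)
    return float(res["test statistic"]), float(res["p-value"])
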