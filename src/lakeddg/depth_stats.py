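"""Statistical comparisons of richness across depths and components.

The central tool is a simultaneous all-pairs (Tukey-type) comparison of
mean richness between depth classes that stays valid under non-normality,
heteroscedasticity, and unequal group sizes: a cell-means linear model with
a heteroscedasticity-consistent (HC3) covariance, and single-step adjusted
p-values from the joint distribution of the maximum |t| statistic.  The
joint distribution is approximated by seeded Monte Carlo from a
multivariate t with the contrasts' correlation matrix and the model's
residual degrees of freedom.

Also here: Pearson correlations between richness components / DDG measures
and the chi-square association between pattern types and components.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise depth contrast from the simultaneous max-t test."""

    label: str
    estimate: float
    se: float
    t: float
    p_unadjusted: float
    p_adjusted: float


def _hc3_cell_means(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Group means and their HC3 variances under the cell-means model.

    In the cell-means parameterisation each coefficient is a group mean with
    leverage 1/n_g for every observation of the group, so the HC3 variance
    of mean_g is sum(e_i^2 / (1 - 1/n_g)^2) / n_g^2.
    """
    means = np.array([g.mean() for g in groups])
    variances = np.empty(len(groups))
    for j, g in enumerate(groups):
        n = len(g)
        e = g - means[j]
        variances[j] = np.sum((e / (1.0 - 1.0 / n)) ** 2) / n**2
    return means, variances


def robust_depth_comparisons(
    observations: pd.DataFrame,
    *,
    group_col: str = "depth_m",
    value_col: str = "value",
    n_mc: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> list[ComparisonResult]:
    """All-pairs robust comparisons of mean `value_col` between groups.

    Parameters
    ----------
    observations
        Long table with one row per observation.
    n_mc
        Monte-Carlo draws for the max-|t| reference distribution.
    seed
        Seed or Generator for the Monte-Carlo draws.

    Returns
    -------
    One :class:`ComparisonResult` per unordered group pair, with single-step
    adjusted p-values (familywise-error controlling).

    Raises
    ------
    ValueError
        If fewer than two groups are present or any group has fewer than
        two observations (its HC3 variance is undefined).
    """
    rng = np.random.default_rng(seed)
    labels = sorted(observations[group_col].unique())
    if len(labels) < 2:
        raise ValueError("need at least two groups to compare")
    groups = [
        np.asarray(observations.loc[observations[group_col] == g, value_col], float)
        for g in labels
    ]
    sizes = [len(g) for g in groups]
    if min(sizes) < 2:
        small = labels[int(np.argmin(sizes))]
        raise ValueError(f"group {small!r} has fewer than two observations")

    means, variances = _hc3_cell_means(groups)
    df_resid = sum(sizes) - len(labels)

    pairs = list(combinations(range(len(labels)), 2))
    m = len(pairs)
    est = np.array([means[b] - means[a] for a, b in pairs])
    var = np.array([variances[a] + variances[b] for a, b in pairs])
    se = np.sqrt(var)

    # t statistics; a zero SE with a zero estimate is an exact tie (t = 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, est / np.where(se > 0, se, 1.0), np.where(est == 0, 0.0, np.inf))

    p_unadj = 2.0 * stats.t.sf(np.abs(t), df_resid)

    if m == 1:
        p_adj = p_unadj.copy()
    else:
        # Correlation of the contrast estimates (covariances share group terms)
        cov = np.zeros((m, m))
        for i, (a, b) in enumerate(pairs):
            for j, (c, d) in enumerate(pairs):
                cov[i, j] = (
                    variances[a] * ((a == c) - (a == d))
                    + variances[b] * ((b == d) - (b == c))
                )
        denom = np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        with np.errstate(invalid="ignore"):
            corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
        np.fill_diagonal(corr, 1.0)
        # Multivariate t draws: correlated normals over a shared chi2 scale
        L = np.linalg.cholesky(corr + 1e-12 * np.eye(m))
        z = rng.standard_normal((n_mc, m)) @ L.T
        scale = np.sqrt(rng.chisquare(df_resid, n_mc) / df_resid)
        max_abs = np.abs(z).max(axis=1) / scale
        p_adj = np.array([np.mean(max_abs >= abs(tj)) if np.isfinite(tj) else 0.0 for tj in t])
        p_adj = np.maximum(p_adj, p_unadj)  # single-step p dominates marginal p

    return [
        ComparisonResult(
            label=f"{labels[b]} - {labels[a]}",
            estimate=float(est[k]),
            se=float(se[k]),
            t=float(t[k]),
            p_unadjusted=float(min(p_unadj[k], 1.0)),
            p_adjusted=float(min(p_adj[k], 1.0)),
        )
        for k, (a, b) in enumerate(pairs)
    ]


def comparisons_frame(results: list[ComparisonResult], alpha: float = 0.05) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contrast": [r.label for r in results],
            "estimate": [r.estimate for r in results],
            "se": [r.se for r in results],
            "t": [r.t for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "significant": [r.p_adjusted < alpha for r in results],
        }
    )


def component_correlations(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between the columns of `table`.

    Returns a long frame with columns (var1, var2, r, p, n).  A column with
    zero variance yields r = NaN and is flagged with p = NaN rather than
    raising, since constant measures do occur (e.g. D_max in a lake whose
    peak never moves).
    """
    cols = list(table.columns)
    rows = []
    for a, b in combinations(cols, 2):
        pair = table[[a, b]].dropna()
        n = len(pair)
        if n < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
            r = p = np.nan
        else:
            r, p = stats.pearsonr(pair[a], pair[b])
        rows.append({"var1": a, "var2": b, "r": r, "p": p, "n": n})
    return pd.DataFrame(rows)


def pattern_component_association(table: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square test on a component x pattern contingency table.

    Returns (statistic, df, p).  Zero margins (an all-zero row or column)
    make the table degenerate and raise.
    """
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table must hold nonnegative integer counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)
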