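"""Additive mixed models for DDG peak measures.

Fits y = b0 + sum_j f_j(x_j) + u_lake + eps, with each f_j a penalized
cubic B-spline (P-spline: equally spaced knots, second-order difference
penalty, sum-to-zero constrained) and u_lake a ridge-penalized random
intercept per lake.  Smoothing parameters — one per smooth plus one for
the random-intercept ridge — are chosen by minimising generalised
cross-validation (GCV) over their logarithms.

Per-term significance uses a Wald-type test on the penalized coefficients
with the Bayesian posterior covariance (XtX + S)^-1 * sigma^2, rank-reduced
to the term's rounded effective degrees of freedom, referred to an F
distribution.  Model selection is backward: refit after removing the least
significant smooth until every remaining smooth has p below the threshold
(default 0.05), possibly leaving an empty (intercept + random effect)
model.

"Deviance explained" is measured on the smooth (fixed) part only, against
the empty model's fixed part, so that a single retained term's drop
contribution equals the model's total explained deviance by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, linalg, optimize, stats

_LOG_LAMBDA_BOUNDS = (-4.0, 9.0)


def _knot_vector(
    x: np.ndarray, n_basis: int, degree: int, domain: tuple[float, float] | None
) -> np.ndarray:
    lo, hi = domain if domain is not None else (x.min(), x.max())
    if hi <= lo:
        raise ValueError("degenerate predictor: no spread in x")
    n_interior = n_basis - degree - 1
    if n_interior < 0:
        raise ValueError(f"n_basis={n_basis} too small for degree {degree}")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]


def bspline_basis(
    x: np.ndarray, n_basis: int = 8, degree: int = 3, domain: tuple[float, float] | None = None
) -> np.ndarray:
    """Cubic B-spline design matrix with equally spaced interior knots."""
    x = np.asarray(x, float)
    t = _knot_vector(x, n_basis, degree, domain)
    xc = np.clip(x, t[0], t[-1])
    return interpolate.BSpline.design_matrix(xc, t, degree).toarray()


def _curvature_penalty(t: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    """Exact integrated squared second derivative of the basis functions.

    For cubic B-splines the integrand is piecewise quadratic, so two-point
    Gauss-Legendre per knot interval integrates it exactly.  The penalty's
    null space is exactly the linear functions of x, so heavy smoothing
    leaves a straight line.
    """
    from scipy.interpolate import splev

    P = np.zeros((n_basis, n_basis))
    gauss = np.array([-1, 1]) / np.sqrt(3)
    breaks = np.unique(t)
    eye = np.eye(n_basis)
    for a, b in zip(breaks[:-1], breaks[1:]):
        xq = (a + b) / 2 + (b - a) / 2 * gauss
        w = (b - a) / 2
        vals = np.array([splev(xq, (t, eye[j], degree), der=2) for j in range(n_basis)])
        P += w * vals @ vals.T
    return P


def _constrained_smooth(B: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Absorb the sum-to-zero constraint: returns (Z, S) with Z = B Q."""
    c = B.sum(axis=0)[None, :]
    # Q spans the null space of c
    q, _ = np.linalg.qr(c.T, mode="complete")
    Q = q[:, 1:]
    S = Q.T @ _curvature_penalty(t, B.shape[1]) @ Q
    return B @ Q, S


@dataclass
class _Design:
    """Assembled design for one additive-model fit."""

    y: np.ndarray
    X: np.ndarray
    blocks: dict[str, slice]  # term name -> column slice (incl. "_re_")
    penalties: dict[str, np.ndarray]  # term name -> penalty block
    term_names: list[str]  # smooth terms in design order
    has_re: bool


def _assemble(
    y: np.ndarray,
    smooths: dict[str, np.ndarray],
    groups: np.ndarray | None,
    n_basis: int,
) -> _Design:
    n = len(y)
    cols: list[np.ndarray] = [np.ones((n, 1))]
    blocks: dict[str, slice] = {}
    penalties: dict[str, np.ndarray] = {}
    start = 1
    for name, x in smooths.items():
        x = np.asarray(x, float)
        t = _knot_vector(x, n_basis, 3, None)
        B = bspline_basis(x, n_basis=n_basis)
        Z, S = _constrained_smooth(B, t)
        cols.append(Z)
        blocks[name] = slice(start, start + Z.shape[1])
        penalties[name] = S
        start += Z.shape[1]
    has_re = groups is not None
    if has_re:
        labels, idx = np.unique(groups, return_inverse=True)
        G = np.zeros((n, len(labels)))
        G[np.arange(n), idx] = 1.0
        cols.append(G)
        blocks["_re_"] = slice(start, start + len(labels))
        penalties["_re_"] = np.eye(len(labels))
        start += len(labels)
    return _Design(
        y=np.asarray(y, float),
        X=np.hstack(cols),
        blocks=blocks,
        penalties=penalties,
        term_names=list(smooths),
        has_re=has_re,
    )


@dataclass
class AdditiveFit:
    """A fitted penalized additive model with random intercept."""

    design: _Design
    beta: np.ndarray
    lambdas: dict[str, float]
    edf: dict[str, float]
    edf_total: float
    sigma2: float
    cov_beta: np.ndarray  # Bayesian posterior covariance
    gcv: float

    @property
    def fitted(self) -> np.ndarray:
        return self.design.X @ self.beta

    @property
    def fitted_fixed(self) -> np.ndarray:
        """Fitted values from intercept + smooths only (no random effect)."""
        X = self.design.X.copy()
        if self.design.has_re:
            X = X[:, : self.design.blocks["_re_"].start]
            return X @ self.beta[: self.design.blocks["_re_"].start]
        return X @ self.beta

    @property
    def rss(self) -> float:
        r = self.design.y - self.fitted
        return float(r @ r)

    @property
    def rss_fixed(self) -> float:
        r = self.design.y - self.fitted_fixed
        return float(r @ r)

    @property
    def re_variance(self) -> float:
        """Random-intercept variance sigma_b^2 = sigma^2 / lambda_re."""
        if not self.design.has_re:
            return 0.0
        return self.sigma2 / self.lambdas["_re_"]

    def adj_r2(self) -> float:
        y = self.design.y
        n = len(y)
        tss = float(((y - y.mean()) ** 2).sum())
        if tss == 0:
            return 0.0
        return 1.0 - (self.rss / max(n - self.edf_total, 1.0)) / (tss / (n - 1))

    def term_pvalue(self, name: str) -> float:
        """Wald-type F test of a smooth term on the function scale.

        Tests f_j = 0 with T = f' V_f^- f, where f is the term's fitted
        contribution at the data and V_f^- the pseudo-inverse of its
        posterior covariance truncated to the term's rounded effective
        degrees of freedom; T/r is referred to F(r, n - edf_total).
        """
        sl = self.design.blocks[name]
        Z = self.design.X[:, sl]
        b = self.beta[sl]
        f = Z @ b
        Vf_half = Z @ np.linalg.cholesky(
            self.cov_beta[sl, sl] + 1e-12 * np.eye(sl.stop - sl.start)
        )
        # nonzero eigenpairs of V_f via the small coefficient-space gram
        gram = Vf_half.T @ Vf_half
        w, U = np.linalg.eigh(gram)
        order = np.argsort(w)[::-1]
        w, U = w[order], U[:, order]
        # ceil rank is deliberately conservative for penalized terms
        r = int(np.clip(np.ceil(self.edf[name]), 1, len(b)))
        w = w[:r]
        # eigenvectors of V_f on the data scale, orthonormal
        with np.errstate(divide="ignore", invalid="ignore"):
            Uf = Vf_half @ U[:, :r] / np.sqrt(np.maximum(w, 1e-300))
        proj = Uf.T @ f
        T = float((proj**2 / np.maximum(w, 1e-12)).sum())
        df2 = max(len(self.design.y) - self.edf_total, 1.0)
        return float(stats.f.sf(T / r, r, df2))


def _penalty_matrix(design: _Design, lambdas: dict[str, float]) -> np.ndarray:
    p = design.X.shape[1]
    S = np.zeros((p, p))
    for name, block in design.penalties.items():
        sl = design.blocks[name]
        S[sl, sl] += lambdas[name] * block
    return S


def _solve(design: _Design, lambdas: dict[str, float]):
    XtX = design.X.T @ design.X
    Xty = design.X.T @ design.y
    S = _penalty_matrix(design, lambdas)
    A = XtX + S
    cf = linalg.cho_factor(A + 1e-10 * np.eye(len(A)))
    beta = linalg.cho_solve(cf, Xty)
    F = linalg.cho_solve(cf, XtX)  # influence on coefficient scale
    Ainv = linalg.cho_solve(cf, np.eye(len(A)))
    return beta, F, Ainv


def fit_additive(
    y: np.ndarray,
    smooths: dict[str, np.ndarray],
    groups: np.ndarray | None = None,
    n_basis: int = 8,
    fixed_lambdas: dict[str, float] | None = None,
    method: str = "REML",
) -> AdditiveFit:
    """Fit the penalized additive model, selecting smoothing by REML or GCV.

    `fixed_lambdas` pins selected penalties (by term name, "_re_" for the
    random intercept); the remaining ones are optimized.
    """
    design = _assemble(np.asarray(y, float), smooths, groups, n_basis)
    n, p = design.X.shape
    if n < 10:
        raise ValueError("need at least 10 observations")

    fixed_lambdas = dict(fixed_lambdas or {})
    free = [name for name in design.penalties if name not in fixed_lambdas]

    # penalty ranks, for the REML log-determinant of the penalty
    ranks = {
        name: int(np.sum(np.linalg.eigvalsh(S) > 1e-9 * max(np.linalg.eigvalsh(S).max(), 1)))
        for name, S in design.penalties.items()
    }
    n_unpenalized = design.X.shape[1] - sum(ranks.values())

    def lambdas_from(logs: np.ndarray) -> dict[str, float]:
        lam = {name: 10.0 ** float(v) for name, v in zip(free, logs)}
        lam.update(fixed_lambdas)
        return lam

    def criterion(logs: np.ndarray) -> float:
        lam = lambdas_from(np.clip(logs, *_LOG_LAMBDA_BOUNDS))
        S = _penalty_matrix(design, lam)
        A = design.X.T @ design.X + S + 1e-10 * np.eye(design.X.shape[1])
        try:
            cf = linalg.cho_factor(A)
        except linalg.LinAlgError:
            return 1e12
        beta = linalg.cho_solve(cf, design.X.T @ design.y)
        resid = design.y - design.X @ beta
        pen_rss = float(resid @ resid + beta @ S @ beta)
        if method == "REML":
            # restricted marginal likelihood, sigma^2 profiled out
            logdet_A = 2.0 * np.sum(np.log(np.diag(cf[0])))
            logdet_S = sum(ranks[name] * np.log(lam[name]) for name in lam)
            df = max(n - n_unpenalized, 1)
            return df * np.log(pen_rss / df) + logdet_A - logdet_S
        # GCV
        F = linalg.cho_solve(cf, design.X.T @ design.X)
        rss = float(resid @ resid)
        denom = max(n - float(np.trace(F)), 1e-3)
        return n * rss / denom**2

    if free:
        best_logs, best_val = None, np.inf
        for x0 in (np.full(len(free), 1.0), np.full(len(free), 4.0)):
            res = optimize.minimize(
                criterion,
                x0,
                method="L-BFGS-B",
                bounds=[_LOG_LAMBDA_BOUNDS] * len(free),
                options={"maxiter": 200, "ftol": 1e-10},
            )
            if res.fun < best_val:
                best_logs, best_val = res.x, res.fun
        lambdas = lambdas_from(np.clip(best_logs, *_LOG_LAMBDA_BOUNDS))
        gcv_val = best_val
    else:
        lambdas = dict(fixed_lambdas)
        gcv_val = criterion(np.array([]))

    beta, F, Ainv = _solve(design, lambdas)
    resid = design.y - design.X @ beta
    rss = float(resid @ resid)
    edf_diag = np.diag(F)
    edf = {name: float(edf_diag[sl].sum()) for name, sl in design.blocks.items()}
    edf["_intercept_"] = float(edf_diag[0])
    edf_total = float(np.trace(F))
    sigma2 = rss / max(n - edf_total, 1.0)
    return AdditiveFit(
        design=design,
        beta=beta,
        lambdas=lambdas,
        edf=edf,
        edf_total=edf_total,
        sigma2=sigma2,
        cov_beta=Ainv * sigma2,
        gcv=gcv_val,
    )


@dataclass
class GAMMResult:
    """Minimal model for one response after backward elimination."""

    response: str
    retained: list[str]
    p_values: dict[str, float]  # retained terms, selection-adjusted
    raw_p_values: dict[str, float]  # retained terms, unadjusted
    edf: dict[str, float]
    adj_r2: float
    deviance_explained: float  # percent, smooth part vs empty model
    drop_contribution: dict[str, float]  # percent of deviance explained
    re_variance: float
    sigma2: float
    eliminated: list[tuple[str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "retained": self.retained,
            "p_values": self.p_values,
            "raw_p_values": self.raw_p_values,
            "edf": {k: self.edf[k] for k in self.retained},
            "adj_r2": self.adj_r2,
            "deviance_explained_pct": self.deviance_explained,
            "drop_contribution_pct": self.drop_contribution,
            "random_effect_variance": self.re_variance,
            "sigma2": self.sigma2,
            "eliminated": self.eliminated,
        }


def _deviance_explained(
    y: np.ndarray,
    smooths: dict[str, np.ndarray],
    groups: np.ndarray | None,
    rss_empty: float,
    n_basis: int,
) -> tuple[float, AdditiveFit | None]:
    if not smooths:
        return 0.0, None
    fit = fit_additive(y, smooths, groups, n_basis=n_basis)
    if rss_empty <= 0:
        return 0.0, fit
    return 1.0 - fit.rss_fixed / rss_empty, fit


def fit_gamm(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    group: str = "lake_id",
    threshold: float = 0.05,
    n_basis: int = 8,
) -> GAMMResult:
    """Backward-eliminated additive mixed model for one DDG measure.

    Starts from a full model with one smooth per predictor and a lake
    random intercept, removes the least significant smooth while any has
    p >= `threshold`, and reports per-term p, effective df, adjusted R²,
    deviance explained (smooth part), and per-term drop contribution (the
    percentage-point fall in deviance explained when the term is refitted
    out of the retained model).

    Because backward elimination keeps the most significant of the initial
    candidate axes, the stopping rule uses Sidak-adjusted term p-values,
    1 - (1 - p)^m0 with m0 the initial number of candidates, so the
    probability of retaining any spurious axis is controlled at the
    threshold.  Raw per-term p-values are reported alongside.

    Raises
    ------
    ValueError
        With fewer than 10 campaigns or fewer than 3 lakes.
    """
    sub = data[[response, group, *predictors]].dropna()
    if len(sub) < 10:
        raise ValueError(f"need >= 10 campaigns, got {len(sub)}")
    if sub[group].nunique() < 3:
        raise ValueError(f"need >= 3 lakes, got {sub[group].nunique()}")
    y = sub[response].to_numpy(float)
    groups = sub[group].to_numpy()
    xs = {p: sub[p].to_numpy(float) for p in predictors}

    # empty-model baseline: intercept + random intercept, fixed part only
    empty = fit_additive(y, {}, groups)
    rss_empty = empty.rss_fixed

    m0 = max(len(predictors), 1)
    current = list(predictors)
    eliminated: list[tuple[str, float]] = []
    raw: dict[str, float] = {}
    while current:
        fit = fit_additive(y, {p: xs[p] for p in current}, groups, n_basis=n_basis)
        raw = {p: fit.term_pvalue(p) for p in current}
        pvals = {p: 1.0 - (1.0 - rp) ** m0 for p, rp in raw.items()}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < threshold:
            break
        eliminated.append((worst, float(pvals[worst])))
        current.remove(worst)
    else:
        fit, pvals, raw = empty, {}, {}

    dev_full, _ = _deviance_explained(
        y, {p: xs[p] for p in current}, groups, rss_empty, n_basis
    )
    drop: dict[str, float] = {}
    for p in current:
        rest = [q for q in current if q != p]
        dev_rest, _ = _deviance_explained(
            y, {q: xs[q] for q in rest}, groups, rss_empty, n_basis
        )
        drop[p] = 100.0 * max(dev_full - dev_rest, 0.0)

    return GAMMResult(
        response=response,
        retained=current,
        p_values={p: float(pvals[p]) for p in current},
        raw_p_values={p: float(raw[p]) for p in current},
        edf={p: fit.edf[p] for p in current},
        adj_r2=fit.adj_r2(),
        deviance_explained=100.0 * dev_full,
        drop_contribution=drop,
        re_variance=fit.re_variance,
        sigma2=fit.sigma2,
        eliminated=eliminated,
    )
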