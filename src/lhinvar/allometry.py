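"""Criteria 3 and 4: log-log regressions of traits on body mass.

A power law C = a·S^b becomes the straight line
log10 C = log10(a) + b·log10 S, so the OLS/PGLS slope is the scaling
exponent b and the intercept is log10 a.  Type II invariance asks for a
slope indistinguishable from zero (nonsignificant in both OLS and PGLS)
together with a coefficient of determination below 0.05.

PGLS here is generalized least squares with error covariance
sigma^2 · W(lambda), where W is the Brownian-motion covariance of the tree
with its off-diagonals scaled by Pagel's lambda.  On non-ultrametric trees
the tip residual variances are fixed proportional to root-to-tip depth
("depth-proportional" weights) — with BM correlations this makes W(lambda)
exactly the lambda-scaled BM covariance matrix.  With "uniform" weights W
is the lambda-scaled BM *correlation* matrix (equal tip variances).
Lambda is estimated by maximum likelihood profiled over a grid and refined
by bounded scalar minimization; inference on the coefficients is
conditional on the fitted lambda, with t-based intervals on n - 2 degrees
of freedom, mirroring standard comparative-methods practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .phylo import PhyloCov, to_correlation
from .trait_io import InsufficientSample

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OLSFit:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    r2: float
    adj_r2: float
    p_slope: float
    df: int
    n: int

    def __post_init__(self):
        assert -1e-12 <= self.r2 <= 1 + 1e-12
        assert self.adj_r2 <= self.r2 + 1e-12
        assert self.slope_ci[0] <= self.slope <= self.slope_ci[1]


def ols_fit(x, y, min_n: int = 3, alpha: float = 0.05) -> OLSFit:
    """Ordinary least squares of y on x with t-based 95% intervals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    if x.size < min_n:
        raise InsufficientSample(f"OLS needs n >= {min_n}, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=alpha)
    return OLSFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        p_slope=float(res.pvalues[1]),
        df=int(res.df_resid),
        n=int(x.size),
    )


@dataclass(frozen=True)
class PGLSFit:
    slope: float | None
    intercept: float
    slope_ci: tuple[float, float] | None
    intercept_ci: tuple[float, float]
    p_slope: float | None
    lam: float
    loglik: float
    n: int
    lam_bound_hit: bool = False


def _gls(X: np.ndarray, y: np.ndarray, W: np.ndarray):
    """GLS estimates, RSS and log-determinant via Cholesky whitening."""
    try:
        L = np.linalg.cholesky(W)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular weight matrix (near-duplicate taxa?)"
        ) from exc
    # whiten: L^{-1} X, L^{-1} y
    Xt = solve_triangular(L, X, lower=True)
    yt = solve_triangular(L, y, lower=True)
    beta, _, _, _ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    XtX = Xt.T @ Xt
    return beta, rss, logdet, XtX


def _profile_loglik(lam, X, y, cov, uniform_weights, reml):
    W = _weight_matrix(cov, lam, uniform_weights)
    n, p = X.shape
    beta, rss, logdet, XtX = _gls(X, y, W)
    if reml:
        s2 = rss / (n - p)
        _, ld2 = np.linalg.slogdet(XtX)
        return (
            -0.5 * (n - p) * (np.log(2 * np.pi * s2) + 1)
            - 0.5 * logdet - 0.5 * ld2
        )
    s2 = rss / n
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1) - 0.5 * logdet


def _weight_matrix(cov: PhyloCov, lam: float, uniform_weights: bool):
    base = to_correlation(cov) if uniform_weights else cov.V
    W = base * lam
    np.fill_diagonal(W, np.diag(base))
    return W


def pgls_fit(
    x,
    y,
    cov: PhyloCov,
    weights_mode: str = "depth",
    lam: float | None = None,
    lam_bounds: tuple[float, float] = (0.0, 1.0),
    reml: bool = False,
    min_n: int = 3,
    alpha: float = 0.05,
    grid_points: int = 51,
) -> PGLSFit:
    """Phylogenetic GLS of y on x under a Pagel-lambda error structure.

    ``cov`` must already be restricted to, and ordered like, the (x, y)
    sample.  ``x=None`` fits an intercept-only model (used for the GLS
    mean).  ``lam=None`` profiles the likelihood over ``lam_bounds`` on a
    grid of ``grid_points`` then refines with bounded minimization; a fixed
    ``lam`` skips estimation.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if cov.V.shape[0] != n:
        raise ValueError("covariance size does not match sample")
    if n < min_n:
        raise InsufficientSample(f"PGLS needs n >= {min_n}, got {n}")
    if weights_mode not in ("depth", "uniform"):
        raise ValueError(f"unknown weights_mode {weights_mode!r}")
    uniform = weights_mode == "uniform"
    if x is None:
        X = np.ones((n, 1))
    else:
        x = np.asarray(x, dtype=float)
        if np.ptp(x) == 0:
            raise ValueError("x is constant; slope undefined")
        X = np.column_stack([np.ones(n), x])

    bound_hit = False
    if lam is None:
        lo, hi = lam_bounds
        grid = np.linspace(lo, hi, grid_points)
        lls = np.array([
            _profile_loglik(l, X, y, cov, uniform, reml) for l in grid
        ])
        k = int(np.argmax(lls))
        a = grid[max(k - 1, 0)]
        b = grid[min(k + 1, grid_points - 1)]
        if a < b:
            res = optimize.minimize_scalar(
                lambda l: -_profile_loglik(l, X, y, cov, uniform, reml),
                bounds=(a, b), method="bounded",
                options={"xatol": 1e-6},
            )
            lam_hat = float(res.x)
            if -res.fun < lls[k]:  # keep the grid optimum if refinement lost
                lam_hat = float(grid[k])
        else:
            lam_hat = float(grid[k])
        if min(abs(lam_hat - lo), abs(lam_hat - hi)) < 1e-6:
            bound_hit = True
            log.warning("lambda estimate at bound (%.3f)", lam_hat)
    else:
        lam_hat = float(lam)

    W = _weight_matrix(cov, lam_hat, uniform)
    beta, rss, logdet, XtX = _gls(X, y, W)
    ll = _profile_loglik(lam_hat, X, y, cov, uniform, reml)
    p = X.shape[1]
    dof = n - 2 if x is not None else n - 1  # t degrees of freedom
    s2 = rss / max(n - p, 1)
    cov_beta = s2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov_beta))
    tq = stats.t.ppf(1 - alpha / 2, dof)

    intercept = float(beta[0])
    intercept_ci = (intercept - tq * se[0], intercept + tq * se[0])
    if x is None:
        return PGLSFit(None, intercept, None, intercept_ci, None,
                       lam_hat, float(ll), n, bound_hit)
    slope = float(beta[1])
    tstat = slope / se[1] if se[1] > 0 else np.inf
    p_slope = float(2 * stats.t.sf(abs(tstat), dof))
    return PGLSFit(
        slope=slope,
        intercept=intercept,
        slope_ci=(slope - tq * se[1], slope + tq * se[1]),
        intercept_ci=intercept_ci,
        p_slope=p_slope,
        lam=lam_hat,
        loglik=float(ll),
        n=n,
        lam_bound_hit=bound_hit,
    )


@dataclass(frozen=True)
class Type2Verdict:
    """Conjunction rule for type II invariance."""

    pass_r2: bool
    pass_ols_slope: bool
    pass_pgls_slope: bool | None  # None when PGLS unavailable
    degraded: bool = False  # True when decided from OLS alone

    @property
    def verdict_type2(self) -> bool | None:
        if self.pass_pgls_slope is None and not self.degraded:
            return None  # not available
        parts = [self.pass_r2, self.pass_ols_slope]
        if self.pass_pgls_slope is not None:
            parts.append(self.pass_pgls_slope)
        return all(parts)


def evaluate_type2(
    ols: OLSFit,
    pgls: PGLSFit | None,
    alpha: float = 0.05,
    r2_max: float = 0.05,
    degraded_ok: bool = False,
) -> Type2Verdict:
    """Type II verdict: R² < r2_max AND both slopes nonsignificant.

    With ``pgls=None`` the verdict is unavailable unless ``degraded_ok``
    allows deciding from OLS alone (flagged as degraded).
    """
    return Type2Verdict(
        pass_r2=ols.r2 < r2_max,
        pass_ols_slope=ols.p_slope >= alpha,
        pass_pgls_slope=None if pgls is None else pgls.p_slope >= alpha,
        degraded=pgls is None and degraded_ok,
    )
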