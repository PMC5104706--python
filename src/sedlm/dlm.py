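"""Distributed-lag Poisson regression.

The reduced model fitted to an observed (or simulated) series:

    log E[y_t] = alpha + sum_{i=0}^{L} beta_i X_{t-i} + seasonal block

The lag coefficients may be unconstrained, restricted to a polynomial of
degree p (beta_i = sum_j beta*_j i^j, the Almon restriction) or to a
cubic B-spline basis over the lag axis.  Either restriction is expressed
as an (L+1)×(J+1) matrix C with beta = C beta*; the model is then fitted
on the transformed regressors X* = Xlag C.  The sum of the lag
coefficients, sum_i beta_i = (column sums of C)·beta*, is the
conventional total-effect estimate whose bias the simulation-enhanced
estimator corrects.

Fitting is iteratively reweighted least squares (log link, canonical
Poisson), with a cached-design fast path for simulation campaigns where
the design matrix is fixed and only the response changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .baseline import SeasonalSpec, build_seasonal_design, _check_rank, FittingError

__all__ = [
    "DLMSpec",
    "LagBasis",
    "DLMFit",
    "build_lag_design",
    "fit_dlm",
    "irls_poisson",
    "DLMDesignCache",
]

IRLS_TOL = 1e-8
IRLS_MAXITER = 100


# ---------------------------------------------------------------------------
# restrictions

def parse_restriction(text: str):
    """Parse 'none', 'poly:4' or 'bspline:5' into a restriction tuple."""
    if text in (None, "none", ""):
        return ("none",)
    kind, _, arg = text.partition(":")
    if kind == "poly":
        return ("poly", int(arg))
    if kind == "bspline":
        return ("bspline", int(arg))
    raise ValueError(f"unknown restriction {text!r}")


@dataclass
class DLMSpec:
    """A lag-model specification: maximum lag and lag-coefficient restriction.

    restriction : ("none",) | ("poly", degree) | ("bspline", df)

    ``lag_respects_calendar``: cleaned series may have calendar gaps
    (removed outlier/missing days).  By default lags count rows, treating
    the series as contiguous; with this flag, rows whose lag window spans
    a gap are dropped instead.
    """

    max_lag: int
    restriction: tuple = ("none",)
    seasonal: SeasonalSpec = field(default_factory=SeasonalSpec)
    lag_respects_calendar: bool = False

    def __post_init__(self):
        if isinstance(self.restriction, str):
            self.restriction = parse_restriction(self.restriction)
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")
        kind = self.restriction[0]
        if kind == "poly" and self.restriction[1] > self.max_lag:
            raise ValueError("polynomial degree must be <= max_lag")
        if kind == "bspline" and self.restriction[1] > self.max_lag + 1:
            raise ValueError("bspline df must be <= max_lag + 1")

    @property
    def label(self) -> str:
        k = self.restriction[0]
        if k == "none":
            return f"L={self.max_lag}"
        return f"L={self.max_lag} {'p' if k == 'poly' else 'bs'}{self.restriction[1]}"


@dataclass
class LagBasis:
    """(L+1)×(J+1) matrix C mapping restricted coefficients to lag coefficients."""

    transform: np.ndarray

    def __post_init__(self):
        C = np.asarray(self.transform, dtype=float)
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("lag-basis columns are linearly dependent")
        self.transform = C

    @property
    def n_restricted(self) -> int:
        return self.transform.shape[1]

    @property
    def column_sums(self) -> np.ndarray:
        return self.transform.sum(axis=0)


def lag_basis(spec: DLMSpec) -> LagBasis:
    L = spec.max_lag
    kind = spec.restriction[0]
    i = np.arange(L + 1, dtype=float)
    if kind == "none":
        return LagBasis(np.eye(L + 1))
    if kind == "poly":
        p = spec.restriction[1]
        return LagBasis(np.vander(i, p + 1, increasing=True))  # columns i^0..i^p
    # cubic B-spline with df columns, knots equally spaced over [0, L];
    # the basis spans constants, so no intercept-column removal
    df = spec.restriction[1]
    degree = 3
    n_interior = df - (degree + 1)
    if n_interior < 0:
        raise ValueError(f"bspline df must be >= {degree + 1}")
    interior = np.linspace(0, L, n_interior + 2)[1:-1]
    knots = np.concatenate([[0.0] * (degree + 1), interior, [float(L)] * (degree + 1)])
    C = BSpline.design_matrix(i, knots, degree).toarray()
    return LagBasis(C)


def build_lag_design(exposure: np.ndarray, spec: DLMSpec):
    """Restricted lag design block.

    The j-th regressor is ``X*_j(t) = sum_i C_ij X_{t-i}``.  The first L
    rows lack full lag history and are masked out.

    Returns ``(Xstar, valid, basis)``.
    """
    x = np.asarray(exposure, dtype=float)
    L = spec.max_lag
    if L >= len(x):
        raise ValueError(f"max_lag {L} >= series length {len(x)}")
    basis = lag_basis(spec)
    lags = np.column_stack([np.roll(x, i) for i in range(L + 1)])
    Xstar = lags @ basis.transform
    valid = np.ones(len(x), dtype=bool)
    valid[:L] = False
    return Xstar, valid, basis


# ---------------------------------------------------------------------------
# IRLS core

@dataclass
class IRLSResult:
    beta: np.ndarray
    cov: np.ndarray
    deviance: float
    converged: bool
    n_iter: int


def _poisson_deviance(y, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return 2.0 * float(np.sum(term - (y - mu)))


def irls_poisson(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = IRLS_TOL,
    max_iter: int = IRLS_MAXITER,
    beta0: np.ndarray | None = None,
) -> IRLSResult:
    """Poisson log-link maximum likelihood by iteratively reweighted LS.

    Converges when the deviance change falls below
    ``tol * (|deviance| + 0.1)``.  ``beta0`` warm-starts the iteration
    (used by the campaign fast path).
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if beta0 is not None:
        eta = np.clip(X @ beta0, -30, 30)
    else:
        eta = np.log(np.maximum(y, 0.0) + 0.5)
    dev = np.inf
    beta = beta0
    converged = False
    it = 0
    XtW = np.empty((p, n))
    for it in range(1, max_iter + 1):
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        np.multiply(X.T, mu, out=XtW)
        XtWX = XtW @ X
        XtWz = XtW @ z
        try:
            beta = np.linalg.solve(XtWX, XtWz)
        except np.linalg.LinAlgError as e:
            raise FittingError(f"singular weighted normal equations: {e}") from e
        eta = np.clip(X @ beta, -30, 30)
        new_dev = _poisson_deviance(y, np.exp(eta))
        if abs(dev - new_dev) < tol * (abs(new_dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    mu = np.exp(eta)
    np.multiply(X.T, mu, out=XtW)
    cov = np.linalg.inv(XtW @ X)
    return IRLSResult(beta=beta, cov=cov, deviance=dev, converged=converged, n_iter=it)


# ---------------------------------------------------------------------------
# public fit

@dataclass
class DLMFit:
    """A fitted distributed-lag model.

    ``beta_star`` are the restricted coefficients (for an unconstrained
    model they are the L+1 raw lag coefficients); ``beta_lags = C
    beta_star`` and ``sum_of_lags = colsums(C)·beta_star`` follow exactly.
    """

    spec: DLMSpec
    beta_star: np.ndarray
    vcov: np.ndarray
    basis: LagBasis
    converged: bool
    model_df: int
    deviance: float
    alpha: float

    @property
    def beta_lags(self) -> np.ndarray:
        return self.basis.transform @ self.beta_star

    @property
    def sum_of_lags(self) -> float:
        return float(self.basis.column_sums @ self.beta_star)

    @property
    def sum_of_lags_se(self) -> float:
        c = self.basis.column_sums
        return float(np.sqrt(c @ self.vcov @ c))

    def to_dict(self) -> dict:
        return {
            "spec": {"max_lag": self.spec.max_lag,
                     "restriction": list(self.spec.restriction)},
            "beta_star": self.beta_star.tolist(),
            "vcov": self.vcov.tolist(),
            "sum_of_lags": self.sum_of_lags,
            "converged": self.converged,
            "deviance": self.deviance,
        }


class DLMDesignCache:
    """Precomputed design for repeated fits on a fixed exposure/covariate set.

    During a simulation campaign only the death series changes from fit to
    fit; the lag block and the seasonal block are identical.  Building the
    design once and warm-starting each IRLS at the previous solution makes
    the campaign's dominant cost a handful of weighted least-squares
    solves per simulated series.
    """

    def __init__(self, series, spec: DLMSpec):
        self.spec = spec
        Xstar, lag_valid, self.basis = build_lag_design(
            series.frame["exposure"].to_numpy(dtype=float), spec
        )
        Xseas, self.names_seas, seas_valid = build_seasonal_design(series, spec.seasonal)
        self.valid = lag_valid & seas_valid
        if spec.lag_respects_calendar and spec.max_lag > 0:
            day = series.frame["date"].astype("int64").to_numpy() // 86_400_000_000_000
            L = spec.max_lag
            contiguous = np.zeros(len(day), dtype=bool)
            contiguous[L:] = (day[L:] - day[:-L]) == L
            self.valid &= contiguous
            if not self.valid.any():
                raise FittingError(
                    "no rows with a gap-free lag window (lag_respects_calendar)")
        # column order: restricted lag block first, then intercept + smooths
        self.X = np.hstack([Xstar, Xseas])[self.valid]
        self.n_lag_cols = Xstar.shape[1]
        if np.ptp(series.frame["exposure"].to_numpy()) == 0:
            raise FittingError("exposure column is constant (degenerate design)")
        _check_rank(
            self.X,
            [f"lag*[{j}]" for j in range(self.n_lag_cols)] + self.names_seas,
        )
        self._warm = None

    def set_warm_start(self, deaths: np.ndarray) -> None:
        """Fit once and keep the solution as a fixed IRLS starting point.

        The warm start is set once (typically from the observed series)
        and never updated by later fits, so repeated fits are independent
        of the order in which they run.
        """
        y = np.asarray(deaths, dtype=float)[self.valid]
        res = irls_poisson(self.X, y)
        if res.converged:
            self._warm = res.beta

    def fit(self, deaths: np.ndarray, warm_start: bool = True) -> DLMFit:
        y = np.asarray(deaths, dtype=float)[self.valid]
        res = irls_poisson(self.X, y, beta0=self._warm if warm_start else None)
        k = self.n_lag_cols
        return DLMFit(
            spec=self.spec,
            beta_star=res.beta[:k].copy(),
            vcov=res.cov[:k, :k].copy(),
            basis=self.basis,
            converged=res.converged,
            model_df=self.X.shape[1],
            deviance=res.deviance,
            alpha=float(res.beta[k]),  # intercept is first seasonal column
        )


def fit_dlm(series, spec: DLMSpec, deaths: np.ndarray | None = None) -> DLMFit:
    """Fit a distributed-lag Poisson model to a (cleaned) daily series.

    ``deaths`` substitutes a simulated death series for the observed one
    while keeping the series' exposure and covariates.
    """
    cache = DLMDesignCache(series, spec)
    y = series.frame["deaths"].to_numpy(dtype=float) if deaths is None else deaths
    fit = cache.fit(y, warm_start=False)
    if not fit.converged:
        raise FittingError("distributed-lag fit did not converge")
    return fit
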