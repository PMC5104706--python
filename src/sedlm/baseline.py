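"""Seasonal baseline calibration (step 0 of the pipeline).

Fits the conventional seasonal/covariate Poisson GLM for daily mortality,

    log E[deaths_t] = intercept + s1(t) + DOW(t) + s2(Td_t) + s3(T_t) + s4(T_{t-1})

with natural cubic splines (7 df per observed year for the time smooth;
3, 6 and 6 df for dew-point, temperature and lag-1 temperature), and
extracts what the three-state simulator needs: the baseline entry
log-rate ``alpha_entry`` (log of the long-run mean daily deaths — in
equilibrium daily deaths equal daily entries into the frail state) and a
fixed per-day ``seasonal_offset`` such that
``exp(alpha_entry + seasonal_offset_t)`` is the fitted daily mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy

__all__ = ["SeasonalSpec", "BaselineModel", "fit_baseline", "build_seasonal_design"]


class FittingError(RuntimeError):
    pass


@dataclass
class SeasonalSpec:
    """Degrees of freedom of the seasonal/covariate smooths.

    ``time_df_per_year`` is applied as a total of
    ``round(time_df_per_year × observed years)`` basis columns, computed
    from the series' date span.
    """

    time_df_per_year: float = 7.0
    dewpoint_df: int = 3
    temp_df: int = 6
    temp_lag1_df: int = 6
    include_dow: bool = True
    spline_family: str = "natural cubic"

    def validate(self) -> None:
        for name in ("time_df_per_year", "dewpoint_df", "temp_df", "temp_lag1_df"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def total_time_df(self, n_years: float) -> int:
        return int(round(self.time_df_per_year * n_years))


def _cr(x: np.ndarray, df: int) -> np.ndarray:
    """Natural cubic regression spline basis, centered (orthogonal to 1)."""
    return np.asarray(
        patsy.dmatrix(
            "cr(x, df=df, constraints='center') - 1",
            {"x": x, "df": df},
        )
    )


def build_seasonal_design(series, spec: SeasonalSpec):
    """Design matrix of the seasonal block shared by baseline and DLM fits.

    Returns ``(X, names, valid)``: the n×p matrix (intercept first), the
    column names, and a boolean row mask (the first row is invalid because
    of the lag-1 temperature term).
    """
    spec.validate()
    f = series.frame
    n = len(f)
    t = np.arange(n, dtype=float)
    time_df = spec.total_time_df(series.n_years)
    if n < 2 * 365:
        raise FittingError("series shorter than two years; time spline unidentifiable")

    blocks = [np.ones((n, 1))]
    names = ["intercept"]

    tb = _cr(t, time_df)
    blocks.append(tb)
    names += [f"s1(t)[{j}]" for j in range(tb.shape[1])]

    if spec.include_dow:
        dow = f["dow"].to_numpy()
        dummies = np.column_stack([(dow == d).astype(float) for d in range(1, 7)])
        blocks.append(dummies)
        names += [f"dow[{d}]" for d in range(1, 7)]

    td = _cr(f["dewpoint"].to_numpy(dtype=float), spec.dewpoint_df)
    blocks.append(td)
    names += [f"s2(Td)[{j}]" for j in range(td.shape[1])]

    temp = f["temperature"].to_numpy(dtype=float)
    tb3 = _cr(temp, spec.temp_df)
    blocks.append(tb3)
    names += [f"s3(T)[{j}]" for j in range(tb3.shape[1])]

    temp_l1 = np.roll(temp, 1)
    temp_l1[0] = temp[0]  # placeholder; row 0 is masked out
    tb4 = _cr(temp_l1, spec.temp_lag1_df)
    blocks.append(tb4)
    names += [f"s4(T lag1)[{j}]" for j in range(tb4.shape[1])]

    X = np.hstack(blocks)
    valid = np.ones(n, dtype=bool)
    valid[0] = False
    return X, names, valid


def _check_rank(X: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via QR pivoting
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise FittingError(f"rank-deficient design (rank {rank} < {X.shape[1]}); "
                           f"near-collinear terms: {bad or 'unidentified'}")


@dataclass
class BaselineModel:
    """Fitted seasonal baseline.

    Attributes
    ----------
    alpha_entry : float
        Log of the long-run mean observed daily deaths.
    seasonal_offset : ndarray
        Per-day offset with ``exp(alpha_entry + seasonal_offset_t)`` equal
        to the GLM's fitted mean; length = series length (the first day,
        dropped for the lag-1 temperature term, carries the second day's
        value so the simulator gets a full-length offset).
    component_curves : dict
        Centered per-day contribution of each smooth/DOW block.
    """

    alpha_entry: float
    seasonal_offset: np.ndarray
    component_curves: dict
    coefficients: pd.Series
    deviance: float
    model_df: int
    mean_deaths: float
    time_df: int
    restrict_to_time_dow: bool = False

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coefficients, "component": [n.split("[")[0] for n in self.coefficients.index]}
        )


def fit_baseline(series, spec: SeasonalSpec | None = None,
                 offset_terms: str = "full") -> BaselineModel:
    """Fit the seasonal Poisson GLM and derive the simulator inputs.

    Parameters
    ----------
    series : DailySeries
        Cleaned series (centered covariates), at least two years long.
    spec : SeasonalSpec
    offset_terms : {"full", "time_dow"}
        Which fitted components enter the simulator's per-day offset:
        the full linear predictor (default) or only the time smooth and
        day-of-week effects.
    """
    from .dlm import irls_poisson  # shared IRLS core

    spec = spec or SeasonalSpec()
    X, names, valid = build_seasonal_design(series, spec)
    _check_rank(X[valid], names)
    y = series.frame["deaths"].to_numpy(dtype=float)
    fit = irls_poisson(X[valid], y[valid])
    if not fit.converged:
        raise FittingError(f"baseline GLM did not converge in {fit.n_iter} iterations "
                           f"(deviance {fit.deviance:.3g})")
    coefs = pd.Series(fit.beta, index=names)

    eta = np.empty(len(y))
    eta[valid] = X[valid] @ fit.beta
    eta[0] = eta[1]  # pad the masked first day

    components = {}
    start = 1  # skip intercept
    for label, width in _block_widths(names):
        block = X[:, start : start + width] @ fit.beta[start : start + width]
        components[label] = block - block.mean()
        start += width

    if offset_terms == "time_dow":
        eta_used = (
            coefs["intercept"]
            + components.get("s1(t)", 0.0)
            + components.get("dow", 0.0)
        )
        eta_used = np.asarray(eta_used) + (eta[valid].mean() - np.mean(eta_used))
    elif offset_terms == "full":
        eta_used = eta
    else:
        raise ValueError("offset_terms must be 'full' or 'time_dow'")

    mean_deaths = float(y[valid].mean())
    alpha_entry = float(np.log(mean_deaths))
    seasonal_offset = eta_used - alpha_entry

    return BaselineModel(
        alpha_entry=alpha_entry,
        seasonal_offset=np.asarray(seasonal_offset),
        component_curves=components,
        coefficients=coefs,
        deviance=fit.deviance,
        model_df=X.shape[1],
        mean_deaths=mean_deaths,
        time_df=spec.total_time_df(series.n_years),
        restrict_to_time_dow=(offset_terms == "time_dow"),
    )


def _block_widths(names: list):
    """Group design column names into (label, width) blocks, skipping intercept."""
    out = []
    for n in names[1:]:
        label = n.split("[")[0]
        if out and out[-1][0] == label:
            out[-1][1] += 1
        else:
            out.append([label, 1])
    return [(l, w) for l, w in out]
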