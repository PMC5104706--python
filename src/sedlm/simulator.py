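"""Three-state (healthy → frail → dead) stochastic mortality simulator.

The healthy pool is effectively infinite; the frail pool ``m_t`` is small
and dynamic.  Each day ``u_t ~ Poisson(mu_t)`` healthy individuals become
frail ("entry") and ``y_t ~ Binomial(m_t, phi_t)`` frail individuals die
("exit"), with

    log mu_t    = alpha_entry + beta_entry * X_t + seasonal_offset_t
    logit phi_t = alpha_exit  + beta_exit  * X_t
    m_{t+1}     = m_t + u_t - y_t

Exposure raises deaths through two channels: ``beta_entry`` (the
population-level effect, relevant for life expectancy) and ``beta_exit``
(the displacement effect, which only brings deaths in the frail pool
forward by days).  ``mlt`` is the mean lifetime in the frail state:
``phi = 1/(1+mlt)``, so mlt = 0 means same-day death and the process
collapses to a plain Poisson ("two-state") model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

__all__ = ["ThreeStateParams", "mlt_to_phi", "initial_frail_size", "simulate"]

#: linear predictors beyond this magnitude abort the simulation
_LINPRED_LIMIT = 30.0


class SimulationError(RuntimeError):
    pass


def mlt_to_phi(mlt: float) -> float:
    """Daily exit probability for a given mean lifetime in the frail state.

    With a geometric daily-death process where death on the entry day's
    next step is possible, the expected number of additional days survived
    after entry is ``(1-phi)/phi``; setting that equal to ``mlt`` gives
    ``phi = 1/(1+mlt)``.  ``mlt = 0`` yields phi = 1 (immediate death, the
    degenerate two-state case).
    """
    if mlt < 0:
        raise ValueError("mean lifetime must be non-negative")
    return 1.0 / (1.0 + mlt)


def initial_frail_size(mlt: float, mean_deaths: float) -> int:
    """Approximate equilibrium frail-pool size: round(mlt × mean daily deaths).

    In equilibrium expected entries equal expected deaths, so the pool
    size times the exit probability equals the mean daily deaths; the
    product of the mean lifetime and the mean daily deaths is the standard
    substitute for the unknown initial pool.
    """
    if mlt < 0 or mean_deaths < 0:
        raise ValueError("mlt and mean_deaths must be non-negative")
    return max(int(round(mlt * mean_deaths)), 0)


@dataclass
class ThreeStateParams:
    """One simulator configuration.

    ``alpha_exit`` and ``m0`` default from ``mlt`` via
    :func:`mlt_to_phi` / :func:`initial_frail_size`.
    """

    beta_entry: float
    beta_exit: float
    mlt: float
    alpha_entry: float
    seasonal_offset: np.ndarray
    alpha_exit: float | None = None
    m0: int | None = None

    def __post_init__(self):
        if self.mlt < 0:
            raise ValueError("mlt must be non-negative")
        phi = mlt_to_phi(self.mlt)
        if self.alpha_exit is None:
            # logit(1) is +inf for the degenerate mlt=0 case; cap for safety
            self.alpha_exit = float(logit(phi)) if phi < 1.0 else math.inf
        if self.m0 is None:
            self.m0 = initial_frail_size(self.mlt, math.exp(self.alpha_entry))
        if self.m0 < 0:
            raise ValueError("m0 must be non-negative")

    @property
    def phi_base(self) -> float:
        return float(expit(self.alpha_exit))


def _recycle(first_year: np.ndarray, n: int) -> np.ndarray:
    reps = int(np.ceil(n / len(first_year)))
    return np.tile(first_year, reps)[:n]


def simulate(
    params: ThreeStateParams,
    exposure: np.ndarray,
    seed=None,
    burn_in: int | None = None,
    return_frail: bool = False,
    entrants_at_risk_same_day: bool = False,
):
    """Simulate a daily death series from the three-state process.

    Parameters
    ----------
    params : ThreeStateParams
    exposure : ndarray
        Per-day exposure (centered scale), same length as
        ``params.seasonal_offset``.
    seed : int, sequence of int, or numpy Generator
    burn_in : int, optional
        Days prepended (recycling the first year of offset/exposure) and
        discarded, so the frail pool reaches equilibrium before day 0.
        Defaults to ``ceil(5 × mlt)``: ``m0 = mlt × mean deaths`` is only
        approximately the equilibrium pool, and five mean lifetimes remove
        the transient.
    return_frail : bool
        Also return the frail-pool trace ``m_t`` (post burn-in) and the
        entry counts ``u_t``.
    entrants_at_risk_same_day : bool
        If True, day-t entrants may die on day t (they are added to the
        pool before the Binomial draw).  Default follows the update order
        of the pool equation: entrants are first at risk the next day.

    Returns
    -------
    deaths : ndarray of int
        Simulated daily deaths, burn-in removed.
    (deaths, frail, entries) if ``return_frail``.
    """
    offset = np.asarray(params.seasonal_offset, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if offset.shape != exposure.shape:
        raise ValueError("seasonal_offset and exposure must have equal length")
    if burn_in is None:
        burn_in = int(np.ceil(5 * params.mlt))
    if burn_in < 0:
        raise ValueError("burn_in must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if burn_in > 0:
        year = min(len(offset), 365)
        offset = np.concatenate([_recycle(offset[:year], burn_in), offset])
        exposure = np.concatenate([_recycle(exposure[:year], burn_in), exposure])

    eta_entry = params.alpha_entry + params.beta_entry * exposure + offset
    bad = np.abs(eta_entry) > _LINPRED_LIMIT
    if bad.any():
        day = int(np.argmax(bad)) - burn_in
        raise SimulationError(
            f"entry linear predictor overflow (|eta|>{_LINPRED_LIMIT}) on day {day}"
        )
    mu = np.exp(eta_entry)
    if math.isinf(params.alpha_exit):
        phi = np.ones_like(exposure)
    else:
        phi = expit(params.alpha_exit + params.beta_exit * exposure)

    n = len(exposure)
    entries = rng.poisson(mu)
    deaths = np.empty(n, dtype=np.int64)
    frail = np.empty(n, dtype=np.int64)
    m = int(params.m0)
    for t in range(n):
        if entrants_at_risk_same_day:
            m += int(entries[t])
        frail[t] = m
        y = rng.binomial(m, phi[t]) if m > 0 else 0
        deaths[t] = y
        m -= y
        if not entrants_at_risk_same_day:
            m += int(entries[t])
    if return_frail:
        return deaths[burn_in:], frail[burn_in:], entries[burn_in:]
    return deaths[burn_in:]
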