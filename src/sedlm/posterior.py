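"""Approximate posterior over (beta_entry, beta_exit) (step 3).

The fitted coefficient vector of the real-data distributed-lag model is
compared with the smoothed response surfaces: assuming the simulated
coefficient vectors scatter around the surface as multivariate normal
with the local covariance, the likelihood of a candidate (entry, exit)
point a is

    L(a) ∝ exp(−d²(a)/2) / |Σ̂(a)|^{1/2},
    d²(a) = (β̂ − f̂(a))ᵀ Σ̂(a)⁻¹ (β̂ − f̂(a)),

zero outside the envelope.  Dimension constants of the MVN density are
constant over the grid and cancel under normalization, so they are
omitted.  The likelihood is normalized by a Riemann sum over the
evaluation lattice (a uniform prior on the envelope), yielding a
discrete posterior with marginals, posterior-mean/mode point estimates
and highest-posterior-density intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .campaign import Envelope
from .surface import SurfaceSet

__all__ = [
    "PosteriorGrid",
    "mahalanobis_sq",
    "likelihood_grid",
    "normalize_and_summarize",
    "posterior_from_surfaces",
]


class PosteriorError(RuntimeError):
    pass


def mahalanobis_sq(beta_real: np.ndarray, sp) -> float:
    """Squared Mahalanobis distance of the observed coefficient vector
    from one surface point's smoothed mean, in the local covariance metric."""
    r = np.asarray(beta_real, dtype=float) - np.asarray(sp.f_hat, dtype=float)
    try:
        sol = np.linalg.solve(sp.sigma_hat, r)
    except np.linalg.LinAlgError as e:
        raise PosteriorError(
            f"singular local covariance at point {tuple(sp.location)}: {e}"
        ) from e
    d2 = float(r @ sol)
    return max(d2, 0.0)


def log_likelihood_values(beta_real: np.ndarray, surfaces: SurfaceSet) -> np.ndarray:
    """Log of the unnormalized likelihood at every surface lattice point."""
    beta_real = np.asarray(beta_real, dtype=float)
    n = len(surfaces)
    out = np.empty(n)
    for k in range(n):
        sp = surfaces[k]
        sign, logdet = np.linalg.slogdet(sp.sigma_hat)
        if sign <= 0:
            raise PosteriorError(
                f"non-positive-definite covariance at {tuple(sp.location)}"
            )
        out[k] = -0.5 * mahalanobis_sq(beta_real, sp) - 0.5 * logdet
    return out


def likelihood_grid(
    beta_real: np.ndarray, surfaces: SurfaceSet, env: Envelope | None = None
) -> np.ndarray:
    """Unnormalized likelihood values on the surface lattice.

    Values are rescaled by the maximum (a constant factor, harmless under
    normalization) for floating-point safety; points outside the envelope
    get exactly zero.
    """
    env = env or surfaces.envelope
    ll = log_likelihood_values(beta_real, surfaces)
    inside = env.contains(surfaces.points)
    if not np.isfinite(ll[inside]).any():
        raise PosteriorError("no finite likelihood value on the lattice")
    vals = np.exp(ll - ll[inside].max())
    vals[~inside] = 0.0
    if vals.sum() <= 0:
        raise PosteriorError(
            "likelihood vanished everywhere; the observed fit is incompatible "
            "with the envelope"
        )
    return vals


def _marginal(points_1d, density, weight_other, step):
    """Collapse the 2-D density onto one axis; returns (grid, density)."""
    grid = np.unique(points_1d)
    dens = np.zeros(len(grid))
    for k, g in enumerate(grid):
        dens[k] = density[np.isclose(points_1d, g)].sum() * weight_other
    total = dens.sum() * step
    return grid, dens / total


def _hpd(grid: np.ndarray, dens: np.ndarray, step: float, mass: float):
    """Greedy density-ranked HPD set on the discrete lattice.

    Returns a list of (lo, hi) intervals (one if the set is contiguous;
    a warning is emitted otherwise) covering at least ``mass``.
    """
    order = np.argsort(dens)[::-1]
    cum = np.cumsum(dens[order]) * step
    n_keep = int(np.searchsorted(cum, mass) + 1)
    chosen = np.sort(order[:min(n_keep, len(order))])
    breaks = np.where(np.diff(chosen) > 1)[0]
    segments = np.split(chosen, breaks + 1)
    if len(segments) > 1:
        warnings.warn(
            f"HPD set is non-contiguous ({len(segments)} segments)", stacklevel=3
        )
    return [
        (float(grid[s[0]] - step / 2), float(grid[s[-1]] + step / 2))
        for s in segments
    ]


@dataclass
class PosteriorGrid:
    """Normalized discrete posterior over (entry, exit).

    ``density`` integrates to one against the lattice cell areas; the
    marginals each integrate to one on their own axis.  The reported
    point estimate is the posterior mean (the posterior mode is also
    kept).
    """

    points: np.ndarray
    density: np.ndarray
    cell_area: float
    entry_grid: np.ndarray
    marginal_entry: np.ndarray
    exit_grid: np.ndarray
    marginal_exit: np.ndarray
    point_estimate: tuple
    mode: tuple
    hpd_entry: list
    hpd_exit: list
    mass: float
    meta: dict = field(default_factory=dict)

    @property
    def mean_entry(self) -> float:
        return self.point_estimate[0]

    @property
    def mean_exit(self) -> float:
        return self.point_estimate[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "entry": self.points[:, 0],
                "exit": self.points[:, 1],
                "density": self.density,
            }
        )


def normalize_and_summarize(
    values: np.ndarray,
    points: np.ndarray,
    cell_area: float,
    mass: float = 0.95,
) -> PosteriorGrid:
    """Normalize lattice likelihood values into a :class:`PosteriorGrid`.

    ``values`` are non-negative unnormalized likelihoods at ``points``
    (an (n, 2) lattice with uniform cell area).  Normalization is the
    Riemann sum; marginals sum across the other axis; the HPD interval is
    the smallest set of lattice cells holding at least ``mass``.
    """
    values = np.asarray(values, dtype=float)
    points = np.atleast_2d(points)
    if values.min() < 0 or not np.isfinite(values).all():
        raise PosteriorError("likelihood values must be finite and non-negative")
    total = values.sum() * cell_area
    if total <= 0:
        raise PosteriorError("cannot normalize: all likelihood values are zero")
    density = values / total

    entry_grid = np.unique(points[:, 0])
    exit_grid = np.unique(points[:, 1])
    step_e = entry_grid[1] - entry_grid[0] if len(entry_grid) > 1 else 1.0
    step_x = exit_grid[1] - exit_grid[0] if len(exit_grid) > 1 else 1.0

    _, marg_e = _marginal(points[:, 0], density, step_x, step_e)
    _, marg_x = _marginal(points[:, 1], density, step_e, step_x)

    w = density * cell_area
    mean = (float(points[:, 0] @ w), float(points[:, 1] @ w))
    kmax = int(np.argmax(density))
    mode = (float(points[kmax, 0]), float(points[kmax, 1]))

    return PosteriorGrid(
        points=points,
        density=density,
        cell_area=cell_area,
        entry_grid=entry_grid,
        marginal_entry=marg_e,
        exit_grid=exit_grid,
        marginal_exit=marg_x,
        point_estimate=mean,
        mode=mode,
        hpd_entry=_hpd(entry_grid, marg_e, step_e, mass),
        hpd_exit=_hpd(exit_grid, marg_x, step_x, mass),
        mass=mass,
    )


def batch_posterior_means(
    beta_matrix: np.ndarray, surfaces: SurfaceSet
) -> np.ndarray:
    """Posterior-mean (entry, exit) for many coefficient vectors at once.

    Used when scoring every simulation record of a campaign: the surface
    inverses and log-determinants are factorized once, then each record's
    posterior over the lattice is formed and averaged.  Returns an
    (n_records, 2) array.  Equivalent to calling
    :func:`posterior_from_surfaces` per record (tested), just vectorized.
    """
    B = np.atleast_2d(np.asarray(beta_matrix, dtype=float))
    pts = surfaces.points
    n_pts = len(pts)
    sig = surfaces.sigma_hat
    sign, logdet = np.linalg.slogdet(sig)
    if (sign <= 0).any():
        bad = int(np.argmax(sign <= 0))
        raise PosteriorError(
            f"non-positive-definite covariance at {tuple(pts[bad])}"
        )
    inv = np.linalg.inv(sig)
    # d2[r, k] = (B[r]-f[k]) inv[k] (B[r]-f[k])
    diff = B[:, None, :] - surfaces.f_hat[None, :, :]  # (R, K, J1)
    d2 = np.einsum("rkj,kjl,rkl->rk", diff, inv, diff)
    ll = -0.5 * d2 - 0.5 * logdet[None, :]
    ll -= ll.max(axis=1, keepdims=True)
    w = np.exp(ll)
    w /= w.sum(axis=1, keepdims=True)
    return w @ pts


def posterior_from_surfaces(
    beta_real: np.ndarray, surfaces: SurfaceSet, mass: float = 0.95
) -> PosteriorGrid:
    """Full step 3: likelihood on the surface lattice, normalized posterior."""
    vals = likelihood_grid(beta_real, surfaces)
    env = surfaces.envelope
    area = env.h * env.h_y
    grid = normalize_and_summarize(vals, surfaces.points, area, mass)
    grid.meta["lattice"] = "surface test points (cell centers by default)"
    return grid
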