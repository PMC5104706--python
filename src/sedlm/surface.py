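"""Kernel-smoothed response surfaces over the envelope (step 2).

For each restricted lag coefficient j, the expected fitted value is a
smooth surface f_j(beta_entry, beta_exit).  The surfaces are estimated
with an Epanechnikov running-mean smoother whose span equals the grid
cell side h; the local covariance of the fitted coefficients around the
surface is estimated from the kernel-weighted residuals.  Because the
kernel support is one cell length, only records in a test point's own
cell or its (at most eight) neighbouring cells can receive non-zero
weight — records elsewhere contribute exactly zero even if within
distance h, which makes the computation local per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .campaign import CampaignResult, Envelope

__all__ = ["SurfacePoint", "SurfaceSet", "epanechnikov_weight", "smooth_surfaces"]


class SurfaceError(RuntimeError):
    pass


def epanechnikov_weight(a, p, h: float) -> np.ndarray:
    """Epanechnikov kernel weight w = (3/4)(1 − ‖(p−a)/h‖²)₊.

    ``a`` may be an (n, 2) array of sample locations; ``p`` is the test
    point; ``h`` the span (the grid cell side).  Weights lie in
    [0, 3/4] and vanish for Euclidean distance ≥ h.
    """
    if h <= 0:
        raise ValueError("span h must be positive")
    diff = (np.atleast_2d(a) - np.asarray(p, dtype=float)) / h
    u2 = np.einsum("ij,ij->i", diff, diff)
    return 0.75 * np.clip(1.0 - u2, 0.0, None)


@dataclass
class SurfacePoint:
    """Smoothed surface value and local covariance at one (entry, exit) point."""

    location: tuple
    f_hat: np.ndarray
    sigma_hat: np.ndarray
    effective_weight: float


@dataclass
class SurfaceSet:
    """Surfaces evaluated on a lattice of test points.

    Arrays are stacked over points: ``f_hat`` is (n_points, J+1),
    ``sigma_hat`` is (n_points, J+1, J+1).
    """

    points: np.ndarray
    f_hat: np.ndarray
    sigma_hat: np.ndarray
    effective_weight: np.ndarray
    envelope: Envelope
    ridge_scale: float = 1e-10

    def __len__(self) -> int:
        return len(self.points)

    def __getitem__(self, k: int) -> SurfacePoint:
        return SurfacePoint(
            tuple(self.points[k]),
            self.f_hat[k],
            self.sigma_hat[k],
            float(self.effective_weight[k]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat table: point, surface components, packed lower-triangle covariance."""
        J1 = self.f_hat.shape[1]
        out = pd.DataFrame(self.points, columns=["entry", "exit"])
        for j in range(J1):
            out[f"f_{j}"] = self.f_hat[:, j]
        il, jl = np.tril_indices(J1)
        for a, b in zip(il, jl):
            out[f"sigma_{a}_{b}"] = self.sigma_hat[:, a, b]
        out["effective_weight"] = self.effective_weight
        return out


def _regularized(sigma: np.ndarray, ridge_scale: float) -> np.ndarray:
    """Ridge sigma + eps*I with eps = ridge_scale × trace/(J+1)."""
    J1 = sigma.shape[0]
    eps = ridge_scale * np.trace(sigma) / J1
    return sigma + eps * np.eye(J1)


def smooth_surfaces(
    campaign: CampaignResult,
    test_points: np.ndarray,
    records_mask=None,
    ridge_scale: float = 1e-10,
) -> SurfaceSet:
    """Estimate f_hat and the local covariance at each test point.

    Parameters
    ----------
    campaign : CampaignResult
        Supplies the records (locations, fitted coefficient vectors,
        cell indices) and the envelope.
    test_points : (n, 2) array
        Points inside the envelope (e.g. ``envelope.cell_centers(1)``).
    records_mask : boolean array, optional
        Restrict to a training subset (cross-validation folds).  Records
        with failed fits are always excluded.

    Notes
    -----
    The weighted covariance uses the plain normalisation
    Σ w r rᵀ / Σ w (no small-sample correction), and a relative ridge
    ``ridge_scale × trace/(J+1) × I`` is added so near-singular local
    covariances stay invertible downstream.
    """
    env = campaign.envelope
    recs = campaign.records
    mask = recs["fit_ok"].to_numpy(bool)
    if records_mask is not None:
        mask = mask & np.asarray(records_mask, dtype=bool)
    locs = recs.loc[mask, ["true_entry", "true_exit"]].to_numpy(dtype=float)
    beta = campaign.beta_star_matrix(mask)
    ci = recs.loc[mask, "cell_i"].to_numpy()
    cj = recs.loc[mask, "cell_j"].to_numpy()

    test_points = np.atleast_2d(np.asarray(test_points, dtype=float))
    if not env.contains(test_points).all():
        raise ValueError("every test point must lie inside the envelope")
    h = env.h

    # bucket records by cell for the 3x3-neighbourhood lookup
    ncx, ncy = env.n_cells_x, env.n_cells_y
    flat = ci * ncy + cj
    order = np.argsort(flat, kind="stable")
    sorted_flat = flat[order]
    starts = np.searchsorted(sorted_flat, np.arange(ncx * ncy))
    ends = np.searchsorted(sorted_flat, np.arange(ncx * ncy), side="right")

    J1 = beta.shape[1]
    n = len(test_points)
    f_hat = np.empty((n, J1))
    sig = np.empty((n, J1, J1))
    eff = np.empty(n)
    for k, p in enumerate(test_points):
        i0, j0 = env.cell_of(p[0], p[1])
        idx = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                i, j = i0 + di, j0 + dj
                if 0 <= i < ncx and 0 <= j < ncy:
                    c = i * ncy + j
                    idx.append(order[starts[c] : ends[c]])
        idx = np.concatenate(idx) if idx else np.empty(0, dtype=int)
        w = epanechnikov_weight(locs[idx], p, h) if len(idx) else np.empty(0)
        wsum = w.sum()
        if wsum <= 0:
            raise SurfaceError(
                f"no records within span of test point ({p[0]:.4g}, {p[1]:.4g})"
            )
        b = beta[idx]
        f = (w @ b) / wsum
        r = b - f
        sig[k] = _regularized((r.T * w) @ r / wsum, ridge_scale)
        f_hat[k] = f
        eff[k] = wsum
    return SurfaceSet(
        points=test_points,
        f_hat=f_hat,
        sigma_hat=sig,
        effective_weight=eff,
        envelope=env,
        ridge_scale=ridge_scale,
    )
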