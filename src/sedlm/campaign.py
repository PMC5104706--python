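"""Simulation campaign over a gridded (entry, exit) envelope (step 1).

The envelope S is a rectangle of plausible (beta_entry, beta_exit) values
divided into a grid of cells; within each cell a fixed number of
(entry, exit, mean-lifetime) triplets is drawn uniformly, a daily death
series is simulated for each triplet with the real exposure/covariate
series and the fixed seasonal offset, and the reference distributed-lag
model is fitted to each simulated series.  The collected
(truth, fitted-coefficient) records are the raw material for the
response-surface and posterior steps.

Each record's random stream is derived from (campaign seed, record
index), so results are independent of worker count and scheduling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .baseline import BaselineModel
from .dlm import DLMDesignCache, DLMSpec
from .simulator import ThreeStateParams, simulate

__all__ = [
    "Envelope",
    "MLTPrior",
    "CampaignResult",
    "sample_grid",
    "make_folds",
    "run_campaign",
    "SQUARE_ENVELOPE",
    "RECT_ENVELOPE",
]


@dataclass(frozen=True)
class Envelope:
    """Rectangular support for (beta_entry, beta_exit), gridded into cells."""

    entry_min: float = -0.02
    entry_max: float = 0.02
    exit_min: float = -0.02
    exit_max: float = 0.02
    n_cells_x: int = 32
    n_cells_y: int = 32

    def __post_init__(self):
        if not (self.entry_min < self.entry_max and self.exit_min < self.exit_max):
            raise ValueError("envelope must have min < max on both axes")
        if self.n_cells_x < 1 or self.n_cells_y < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def h(self) -> float:
        """Cell side length along the entry axis (= kernel span)."""
        return (self.entry_max - self.entry_min) / self.n_cells_x

    @property
    def h_y(self) -> float:
        return (self.exit_max - self.exit_min) / self.n_cells_y

    @property
    def is_square_celled(self) -> bool:
        return math.isclose(self.h, self.h_y)

    def cell_bounds(self, i: int, j: int):
        return (
            self.entry_min + i * self.h,
            self.entry_min + (i + 1) * self.h,
            self.exit_min + j * self.h_y,
            self.exit_min + (j + 1) * self.h_y,
        )

    def cell_of(self, entry: float, exit_: float):
        i = min(int((entry - self.entry_min) / self.h), self.n_cells_x - 1)
        j = min(int((exit_ - self.exit_min) / self.h_y), self.n_cells_y - 1)
        return i, j

    def cell_centers(self, inner_margin: int = 0) -> np.ndarray:
        """(n, 2) array of cell-center (entry, exit) points.

        ``inner_margin`` drops that many rings of boundary cells (1 ring
        gives the inner (nx−2)×(ny−2) evaluation region that avoids edge
        artefacts of the kernel smoother).
        """
        xs = self.entry_min + (np.arange(self.n_cells_x) + 0.5) * self.h
        ys = self.exit_min + (np.arange(self.n_cells_y) + 0.5) * self.h_y
        m = inner_margin
        xs = xs[m : self.n_cells_x - m]
        ys = ys[m : self.n_cells_y - m]
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return (
            (p[:, 0] >= self.entry_min)
            & (p[:, 0] <= self.entry_max)
            & (p[:, 1] >= self.exit_min)
            & (p[:, 1] <= self.exit_max)
        )

    def inner_mask(self, cell_i, cell_j, margin: int = 1) -> np.ndarray:
        """Mask of records lying in the inner (nx−2m)×(ny−2m) cells."""
        ci = np.asarray(cell_i)
        cj = np.asarray(cell_j)
        return (
            (ci >= margin)
            & (ci < self.n_cells_x - margin)
            & (cj >= margin)
            & (cj < self.n_cells_y - margin)
        )


#: the default square envelope: corners (−0.02, −0.02) and (0.02, 0.02), 32×32
SQUARE_ENVELOPE = Envelope()

#: the larger rectangular envelope: entry ±0.04 at the same cell size
RECT_ENVELOPE = Envelope(entry_min=-0.04, entry_max=0.04, n_cells_x=64, n_cells_y=32)


@dataclass(frozen=True)
class MLTPrior:
    """Prior for the mean lifetime in the frail state (days).

    kind="uniform": U(lo, hi), default U(1, 28).
    kind="shifted_poisson": 1 + Poisson(lam).
    """

    kind: str = "uniform"
    lo: float = 1.0
    hi: float = 28.0
    lam: float = 14.0

    def __post_init__(self):
        if self.kind not in ("uniform", "shifted_poisson"):
            raise ValueError(f"unknown MLT prior kind {self.kind!r}")
        if self.kind == "uniform" and not (0 <= self.lo <= self.hi):
            raise ValueError("uniform MLT prior needs 0 <= lo <= hi")
        if self.kind == "shifted_poisson" and self.lam < 0:
            raise ValueError("shifted_poisson MLT prior needs lam >= 0")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.lo, self.hi, size)
        return 1.0 + rng.poisson(self.lam, size).astype(float)


def sample_grid(env: Envelope, per_cell: int, prior: MLTPrior, seed) -> pd.DataFrame:
    """Draw ``per_cell`` (entry, exit, mlt) triplets uniformly in each cell.

    Returns a DataFrame with columns true_entry, true_exit, mlt, cell_i,
    cell_j, in cell-major order.
    """
    if per_cell < 1:
        raise ValueError("per_cell must be >= 1")
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xA11CE])
    rows = []
    for i in range(env.n_cells_x):
        for j in range(env.n_cells_y):
            lo_e, hi_e, lo_x, hi_x = env.cell_bounds(i, j)
            rows.append(
                pd.DataFrame(
                    {
                        "true_entry": rng.uniform(lo_e, hi_e, per_cell),
                        "true_exit": rng.uniform(lo_x, hi_x, per_cell),
                        "mlt": prior.draw(rng, per_cell),
                        "cell_i": i,
                        "cell_j": j,
                    }
                )
            )
    out = pd.concat(rows, ignore_index=True)
    out.index.name = "record"
    return out


def make_folds(samples: pd.DataFrame, k: int, seed) -> np.ndarray:
    """Assign each record to one of k folds, balanced within every cell.

    With 80 records per cell and k=5 this yields per-cell test groups of
    16 and training sets of 64, the standard cross-validated split.
    """
    counts = samples.groupby(["cell_i", "cell_j"]).size()
    if (counts % k).any():
        raise ValueError(
            f"per-cell record count {counts.iloc[0]} not divisible by {k} folds"
        )
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xF01D5])
    folds = np.empty(len(samples), dtype=np.int8)
    for _, idx in samples.groupby(["cell_i", "cell_j"]).indices.items():
        labels = np.repeat(np.arange(k, dtype=np.int8), len(idx) // k)
        folds[idx] = rng.permutation(labels)
    return folds


@dataclass
class CampaignResult:
    """All simulation records plus the configuration that produced them.

    ``records`` has one row per simulated series: the truth
    (true_entry, true_exit, mlt), its grid cell, its fold, the fitted
    restricted coefficients ``beta_star_*`` and their sum, and a
    convergence flag.
    """

    envelope: Envelope
    dlm_spec: DLMSpec
    records: pd.DataFrame
    seed: int
    n_folds: int
    alpha_entry: float
    meta: dict = field(default_factory=dict)

    @property
    def n_restricted(self) -> int:
        return len([c for c in self.records.columns if c.startswith("beta_star_")])

    def beta_star_matrix(self, mask=None) -> np.ndarray:
        cols = [f"beta_star_{j}" for j in range(self.n_restricted)]
        f = self.records if mask is None else self.records[mask]
        return f[cols].to_numpy(dtype=float)


def _simulate_and_fit(args):
    (index, entry, exit_, mlt, seed, alpha_entry, offset, exposure, cache) = args
    rng = np.random.default_rng([seed & 0x7FFFFFFF, int(index)])
    params = ThreeStateParams(
        beta_entry=entry,
        beta_exit=exit_,
        mlt=mlt,
        alpha_entry=alpha_entry,
        seasonal_offset=offset,
    )
    deaths = simulate(params, exposure, seed=rng)
    try:
        fit = cache.fit(deaths)
        return index, fit.beta_star, fit.sum_of_lags, bool(fit.converged)
    except Exception:
        k = cache.n_lag_cols
        return index, np.full(k, np.nan), np.nan, False


def run_campaign(
    env: Envelope,
    baseline: BaselineModel,
    series,
    dlm_spec: DLMSpec,
    per_cell: int,
    prior: MLTPrior | None = None,
    seed: int = 0,
    n_folds: int = 5,
    workers: int = 1,
    max_failed_fraction: float = 0.01,
) -> CampaignResult:
    """Run the full simulate-and-refit campaign over the envelope.

    The simulator reuses the series' exposure and covariates and the
    baseline's fixed seasonal offset; ``alpha_entry`` is the log of the
    long-run mean observed deaths; the initial frail pool is
    mlt × mean deaths.  Every simulated series is refitted with exactly
    the reference ``dlm_spec``.  Failed fits are flagged, never dropped;
    more than ``max_failed_fraction`` of them aborts the campaign.
    """
    prior = prior or MLTPrior()
    samples = sample_grid(env, per_cell, prior, seed)
    folds = make_folds(samples, n_folds, seed)
    cache = DLMDesignCache(series, dlm_spec)
    cache.set_warm_start(series.frame["deaths"].to_numpy(dtype=float))
    exposure = series.frame["exposure"].to_numpy(dtype=float)
    offset = np.asarray(baseline.seasonal_offset, dtype=float)

    tasks = [
        (
            idx,
            row.true_entry,
            row.true_exit,
            row.mlt,
            int(seed),
            baseline.alpha_entry,
            offset,
            exposure,
            cache,
        )
        for idx, row in enumerate(samples.itertuples(index=False))
    ]
    if workers > 1:
        results = Parallel(n_jobs=workers, batch_size=64)(
            delayed(_simulate_and_fit)(t) for t in tasks
        )
    else:
        results = [_simulate_and_fit(t) for t in tasks]
    results.sort(key=lambda r: r[0])

    k = cache.n_lag_cols
    beta = np.vstack([r[1] for r in results])
    records = samples.copy()
    records["fold"] = folds
    for j in range(k):
        records[f"beta_star_{j}"] = beta[:, j]
    records["sum_of_lags"] = [r[2] for r in results]
    records["fit_ok"] = [r[3] for r in results]

    failed = 1.0 - records["fit_ok"].mean()
    if failed > max_failed_fraction:
        raise RuntimeError(
            f"{failed:.1%} of campaign fits failed (> {max_failed_fraction:.0%}); "
            "check the envelope and simulator configuration"
        )
    if failed > 0:
        warnings.warn(f"{failed:.2%} of campaign fits failed and are flagged")

    return CampaignResult(
        envelope=env,
        dlm_spec=dlm_spec,
        records=records,
        seed=int(seed),
        n_folds=n_folds,
        alpha_entry=baseline.alpha_entry,
        meta={
            "per_cell": per_cell,
            "prior": prior,
            "series_length": len(series),
        },
    )
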