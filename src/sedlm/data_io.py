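"""Daily mortality/exposure series: reading, validation, cleaning, writing.

The common currency of the package is the :class:`DailySeries`: one row per
calendar day with a death count, an exposure concentration (PM10-like,
µg/m³) and two meteorological covariates (temperature and dew-point
temperature, °C).  Cleaning removes outlier/missing days jointly from all
columns and centers the continuous columns; the centering constants are
kept with the series so simulated and observed data share one scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DailySeries",
    "CleaningReport",
    "read_daily_csv",
    "write_daily_csv",
    "clean_series",
]

#: columns a DailySeries frame must carry, in canonical order
COLUMNS = ["date", "deaths", "exposure", "temperature", "dewpoint", "dow"]

#: continuous columns that cleaning centers
CENTERED_COLUMNS = ["exposure", "temperature", "dewpoint"]

DEFAULT_OUTLIER_THRESHOLD = 150.0  # µg/m³


class ValidationError(ValueError):
    """A series violates a DailySeries invariant."""


class ConfigurationError(ValueError):
    """Input file/column configuration is wrong."""


@dataclass
class CleaningReport:
    """What `clean_series` removed and why."""

    n_input: int
    n_removed_outlier: int
    n_removed_missing: int
    removed_dates: list
    outlier_threshold: float
    centers: dict
    note: str = "centering applied after outlier/missing removal"

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed_outlier - self.n_removed_missing


@dataclass
class DailySeries:
    """Daily death counts with exposure and meteorological covariates.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``date`` (datetime), ``deaths`` (non-negative int),
        ``exposure``, ``temperature``, ``dewpoint`` (float), ``dow``
        (day-of-week 0=Monday..6=Sunday, derived from ``date``).
    centers : dict
        Per-column constants that were subtracted from the continuous
        columns; empty for a raw (uncentered) series.  ``column + center``
        recovers the natural scale.
    cleaning_report : CleaningReport, optional
        Present iff the series went through :func:`clean_series`.
    """

    frame: pd.DataFrame
    centers: dict = field(default_factory=dict)
    cleaning_report: CleaningReport | None = None

    def __post_init__(self):
        self.frame = self.frame.reset_index(drop=True)
        self.validate()

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def is_cleaned(self) -> bool:
        return self.cleaning_report is not None

    def raw(self, column: str) -> np.ndarray:
        """Column values on the natural (uncentered) scale."""
        return self.frame[column].to_numpy(dtype=float) + self.centers.get(column, 0.0)

    @property
    def mean_deaths(self) -> float:
        return float(self.frame["deaths"].mean())

    @property
    def n_years(self) -> float:
        """Observed span in years, from the date range."""
        span = self.frame["date"].iloc[-1] - self.frame["date"].iloc[0]
        return (span.days + 1) / 365.25

    def validate(self) -> None:
        f = self.frame
        missing = [c for c in COLUMNS if c not in f.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        if len(f) == 0:
            raise ValidationError("empty series")
        deaths = f["deaths"]
        if deaths.isna().any():
            raise ValidationError("missing death counts")
        if not np.allclose(deaths, np.round(deaths)):
            raise ValidationError("death counts must be integers")
        if (deaths < 0).any():
            bad = f.loc[deaths < 0, "date"].iloc[0]
            raise ValidationError(f"negative death count on {bad}")
        d = f["date"]
        if d.isna().any():
            raise ValidationError("unparseable dates present")
        if not d.is_monotonic_increasing or d.duplicated().any():
            raise ValidationError("dates must be strictly increasing")
        if self.is_cleaned:
            for c in CENTERED_COLUMNS:
                if f[c].isna().any():
                    raise ValidationError(f"cleaned series has missing {c}")

    def copy(self) -> "DailySeries":
        return DailySeries(
            self.frame.copy(), dict(self.centers), self.cleaning_report
        )


def _derive_dow(dates: pd.Series) -> pd.Series:
    return dates.dt.dayofweek.astype("int8")


def read_daily_csv(path, column_map: dict | None = None) -> DailySeries:
    """Read a daily series from CSV.

    Parameters
    ----------
    path : path-like
    column_map : dict, optional
        Maps canonical names (``date``, ``deaths``, ``exposure``,
        ``temperature``, ``dewpoint``) to the file's column names.

    Raises
    ------
    ConfigurationError
        A mapped column is absent from the file.
    ValidationError
        Deaths are negative/non-integer, or dates unparseable.
    """
    column_map = column_map or {}
    raw = pd.read_csv(path)
    frame = pd.DataFrame()
    for canonical in ["date", "deaths", "exposure", "temperature", "dewpoint"]:
        src = column_map.get(canonical, canonical)
        if src not in raw.columns:
            raise ConfigurationError(
                f"column {src!r} (for {canonical!r}) not found in {path}; "
                f"available: {list(raw.columns)}"
            )
        frame[canonical] = raw[src]
    frame["date"] = pd.to_datetime(frame["date"], errors="coerce")
    n_bad = int(frame["date"].isna().sum())
    if n_bad:
        raise ValidationError(f"{n_bad} unparseable dates in {path}")
    if not frame["date"].is_monotonic_increasing:
        warnings.warn("dates out of order; sorting ascending", stacklevel=2)
        frame = frame.sort_values("date", kind="mergesort").reset_index(drop=True)
    frame["dow"] = _derive_dow(frame["date"])
    for c in CENTERED_COLUMNS:
        frame[c] = pd.to_numeric(frame[c], errors="coerce")
    frame["deaths"] = pd.to_numeric(frame["deaths"], errors="raise")
    return DailySeries(frame[COLUMNS])


def write_daily_csv(series: DailySeries, path) -> None:
    """Write the series back in the same dialect (header, ISO-8601 dates).

    Only the data columns are written; centering constants live in the
    in-memory object (and in pipeline metadata), not the CSV.
    """
    out = series.frame.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.drop(columns=["dow"]).to_csv(path, index=False)


def clean_series(
    series: DailySeries, outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD
) -> DailySeries:
    """Remove outlier and missing days jointly; center continuous columns.

    Days whose exposure exceeds ``outlier_threshold`` on the natural scale
    (default 150 µg/m³) and days with any missing field are removed from
    every column, including the death counts.  Exposure, temperature and
    dew-point are then centered to mean zero over the retained rows; the
    subtracted constants accumulate in ``centers`` so the operation is
    idempotent and the natural scale is always recoverable.

    Returns a new :class:`DailySeries` with a ``cleaning_report``.
    """
    if outlier_threshold <= 0:
        raise ValueError("outlier_threshold must be positive")
    f = series.frame
    raw_exposure = series.raw("exposure")
    missing = f[["deaths", "exposure", "temperature", "dewpoint"]].isna().any(axis=1)
    outlier = pd.Series(raw_exposure > outlier_threshold, index=f.index) & ~missing
    keep = ~(missing | outlier)
    if not keep.any():
        raise ValidationError("cleaning removed every row (degenerate input)")
    kept = f.loc[keep].reset_index(drop=True)
    centers = dict(series.centers)
    kept = kept.copy()
    for c in CENTERED_COLUMNS:
        mean = float(kept[c].mean())
        kept[c] = kept[c] - mean
        centers[c] = centers.get(c, 0.0) + mean
    report = CleaningReport(
        n_input=len(f),
        n_removed_outlier=int(outlier.sum()),
        n_removed_missing=int(missing.sum()),
        removed_dates=list(f.loc[~keep, "date"]),
        outlier_threshold=outlier_threshold,
        centers=centers,
    )
    return DailySeries(kept, centers, report)
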