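"""Synthetic Chicago-like daily series for testing and demos.

Emulates the structure of a large-city elderly-mortality dataset: Poisson
daily deaths with a smooth winter-peaked seasonal cycle and day-of-week
effects; an autocorrelated, seasonal PM10-like exposure with occasional
extreme days (>150 µg/m³, so the outlier-cleaning rule is exercised); and
correlated temperature / dew-point sinusoids.  Values are on the natural
scale — pass the result through :func:`sedlm.data_io.clean_series` before
fitting, exactly as with observed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import COLUMNS, DailySeries

__all__ = ["SynthConfig", "generate_daily_series"]

DAYS_PER_YEAR = 365.25


@dataclass
class SinusoidParams:
    """Annual sinusoid: mean + amplitude·cos(2π(t − peak_day)/365.25) + noise."""

    mean: float
    amplitude: float
    noise_sd: float
    peak_day: float = 196.0  # mid-July


@dataclass
class SynthConfig:
    """Configuration of the synthetic daily-series generator.

    Defaults describe an eight-year large-city series for residents aged
    65+: ~100 deaths/day with a 15% (log-scale) winter-peaked seasonal
    swing and small day-of-week effects; PM10 around 35 µg/m³ (sd 18) with
    lag-1 autocorrelation 0.7, a summer-peaked seasonal component and rare
    exponential spikes that push a handful of days past 150 µg/m³;
    temperature and dew-point as correlated annual sinusoids (°C).
    """

    n_years: int = 8
    mean_deaths: float = 100.0
    seasonal_amplitude: float = 0.15  # log scale, peak mid-January
    dow_effects: tuple = (-0.02, 0.01, 0.02, 0.01, 0.0, -0.01, -0.01)
    exposure_mean: float = 35.0
    exposure_sd: float = 18.0
    exposure_ar1: float = 0.7
    exposure_seasonal_amplitude: float = 8.0
    exposure_spike_prob: float = 0.004
    exposure_spike_scale: float = 70.0
    temp_params: SinusoidParams = field(
        default_factory=lambda: SinusoidParams(10.0, 14.0, 4.0)
    )
    dewpoint_params: SinusoidParams = field(
        default_factory=lambda: SinusoidParams(4.0, 12.0, 3.5)
    )
    temp_dewpoint_corr: float = 0.85
    start_date: str = "1987-01-01"
    seed: int = 0

    def validate(self) -> None:
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.mean_deaths <= 0:
            raise ValueError("mean_deaths must be positive")
        if not (0.0 <= self.exposure_ar1 < 1.0):
            raise ValueError("exposure_ar1 must lie in [0, 1)")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Mon..Sun)")
        if not (-1.0 <= self.temp_dewpoint_corr <= 1.0):
            raise ValueError("temp_dewpoint_corr must lie in [-1, 1]")


def _annual_phase(day_of_year: np.ndarray, peak_day: float) -> np.ndarray:
    return np.cos(2.0 * np.pi * (day_of_year - peak_day) / DAYS_PER_YEAR)


def _exposure_series(cfg: SynthConfig, doy: np.ndarray, rng: np.random.Generator):
    n = len(doy)
    seasonal = cfg.exposure_seasonal_amplitude * _annual_phase(doy, 196.0)
    rho = cfg.exposure_ar1
    innov_sd = cfg.exposure_sd * np.sqrt(1.0 - rho**2)
    noise = np.empty(n)
    e = rng.normal(0.0, cfg.exposure_sd)  # stationary start
    for t in range(n):
        e = rho * e + rng.normal(0.0, innov_sd)
        noise[t] = e
    spikes = np.where(
        rng.random(n) < cfg.exposure_spike_prob,
        rng.exponential(cfg.exposure_spike_scale, n),
        0.0,
    )
    return np.maximum(cfg.exposure_mean + seasonal + noise + spikes, 0.0)


def generate_daily_series(cfg: SynthConfig) -> DailySeries:
    """Draw one synthetic :class:`DailySeries` from the configuration.

    Reproducible: the same configuration (including ``seed``) yields an
    identical series on every platform (numpy PCG64 generator).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.n_years * DAYS_PER_YEAR))
    dates = pd.date_range(cfg.start_date, periods=n, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    dow = dates.dayofweek.to_numpy()

    # winter-peaked mortality seasonality (peak mid-January)
    log_mu = (
        np.log(cfg.mean_deaths)
        + cfg.seasonal_amplitude * _annual_phase(doy, 15.0)
        + np.asarray(cfg.dow_effects, dtype=float)[dow]
    )
    deaths = rng.poisson(np.exp(log_mu))

    exposure = _exposure_series(cfg, doy, rng)

    tp, dp = cfg.temp_params, cfg.dewpoint_params
    z_t = rng.normal(size=n)
    z_shared = cfg.temp_dewpoint_corr * z_t + np.sqrt(
        max(0.0, 1.0 - cfg.temp_dewpoint_corr**2)
    ) * rng.normal(size=n)
    temperature = tp.mean + tp.amplitude * _annual_phase(doy, tp.peak_day) + tp.noise_sd * z_t
    dewpoint = dp.mean + dp.amplitude * _annual_phase(doy, dp.peak_day) + dp.noise_sd * z_shared
    # dew point cannot exceed temperature
    dewpoint = np.minimum(dewpoint, temperature)

    frame = pd.DataFrame(
        {
            "date": dates,
            "deaths": deaths.astype(np.int64),
            "exposure": np.round(exposure, 6),
            "temperature": np.round(temperature, 6),
            "dewpoint": np.round(dewpoint, 6),
            "dow": dow.astype("int8"),
        }
    )
    return DailySeries(frame[COLUMNS])
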