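"""Population and time-series statistics for oscillating droplet systems.

Covers the polydispersity index (PDI = σ/μ with the population standard
deviation), per-half droplet volume series, rolling-average denoising, FFT
period estimation, trough-based lag/growth times and droplet number
density.  The period convention: the signal is denoised with a centered
window-3 rolling mean (shrinking windows at the endpoints), z-normalized
(μ = 0, σ = 1, population σ), Fourier transformed, and the period is the
reciprocal of the dominant non-DC frequency.  The lag time is the mean
duration of complete troughs — maximal intervals where the denoised,
normalized signal stays below a threshold (default 0) — and the growth
time is period − lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .size_control import FOUR_THIRDS_PI

__all__ = [
    "WaveSeries",
    "WaveMetrics",
    "NoOscillationError",
    "pdi",
    "half_volumes",
    "rolling_average",
    "period_from_fft",
    "lag_and_growth",
    "number_density",
]


class NoOscillationError(ValueError):
    """Raised when a series carries no oscillatory signal (σ = 0, or no
    complete trough)."""


@dataclass
class WaveSeries:
    """Uniformly sampled total droplet volume in a region of the cell."""

    t: np.ndarray
    v: np.ndarray
    region: str = "whole"  # upper | lower | whole

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.size != self.v.size:
            raise ValueError("t and v must have equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sampling must be uniform")
        if np.any(self.v < 0):
            raise ValueError("volumes must be >= 0")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n(self) -> int:
        return int(self.t.size)


@dataclass
class WaveMetrics:
    """Summary of one oscillating volume series (all times in s)."""

    period: float = np.nan
    lag_time: float = np.nan
    growth_time: float = np.nan
    dominant_frequency: float = np.nan


def pdi(radii) -> float:
    """Polydispersity index σ/μ (population standard deviation)."""
    r = np.asarray(radii, dtype=float)
    if r.size == 0:
        raise ValueError("pdi of an empty set is undefined")
    mu = r.mean()
    if mu == 0:
        raise ValueError("pdi undefined for zero mean radius")
    return float(r.std(ddof=0) / mu)


def half_volumes(tracks: pd.DataFrame, z_center: float = 0.0,
                 radius_col: str = "R") -> tuple[WaveSeries, WaveSeries]:
    """Split the total droplet volume at the cell's equatorial plane.

    ``tracks`` needs columns t, z and a radius column.  A droplet exactly
    on the plane goes to the lower half (deterministic tie-break).
    Returns (upper, lower) series on the common time grid.
    """
    if radius_col not in tracks and "radius" in tracks:
        radius_col = "radius"
    vol = FOUR_THIRDS_PI * tracks[radius_col].to_numpy(dtype=float) ** 3
    upper = tracks["z"].to_numpy(dtype=float) > z_center
    df = pd.DataFrame({"t": tracks["t"].to_numpy(dtype=float), "vol": vol, "upper": upper})
    grid = np.unique(df["t"])
    up = df[df["upper"]].groupby("t")["vol"].sum().reindex(grid, fill_value=0.0)
    lo = df[~df["upper"]].groupby("t")["vol"].sum().reindex(grid, fill_value=0.0)
    return (
        WaveSeries(grid, up.to_numpy(), region="upper"),
        WaveSeries(grid, lo.to_numpy(), region="lower"),
    )


def rolling_average(v: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered rolling mean with shrinking windows at the endpoints."""
    s = pd.Series(np.asarray(v, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def _normalized(series: WaveSeries, window: int) -> np.ndarray:
    sm = rolling_average(series.v, window)
    sigma = sm.std(ddof=0)
    if sigma == 0:
        raise NoOscillationError("flat series: no oscillation")
    return (sm - sm.mean()) / sigma


def period_from_fft(series: WaveSeries, window: int = 3) -> WaveMetrics:
    """Oscillation period from the dominant FFT frequency.

    Denoise (rolling mean, window 3) → z-normalize → real FFT → take the
    non-DC frequency of largest magnitude (ties towards lower frequency)
    → period = 1/f.  Raises NoOscillationError on a flat series.
    """
    if series.n < 8:
        raise ValueError("need at least 8 samples")
    z = _normalized(series, window)
    mag = np.abs(np.fft.rfft(z))
    freqs = np.fft.rfftfreq(series.n, d=series.dt)
    k = 1 + int(np.argmax(mag[1:]))  # argmax returns the first (lowest-f) tie
    f = freqs[k]
    return WaveMetrics(period=1.0 / f, dominant_frequency=float(f))


def _crossings(z: np.ndarray, t: np.ndarray, threshold: float) -> list[tuple[float, float]]:
    """Complete below-threshold intervals with interpolated edge times."""
    below = z < threshold
    intervals = []
    i = 0
    n = z.size
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if i > 0 and j < n - 1:  # complete trough only
                # linear interpolation of the crossing instants
                t0 = np.interp(threshold, [z[i], z[i - 1]], [t[i], t[i - 1]])
                t1 = np.interp(threshold, [z[j], z[j + 1]], [t[j], t[j + 1]])
                intervals.append((t0, t1))
            i = j + 1
        else:
            i += 1
    return intervals


def lag_and_growth(series: WaveSeries, metrics: WaveMetrics,
                   threshold: float | None = None, window: int = 3) -> WaveMetrics:
    """Mean trough duration (lag) and growth time = period − lag.

    Troughs are maximal intervals where the denoised, z-normalized signal
    is below a threshold; only complete troughs (both edges inside the
    series) are averaged, with edge instants linearly interpolated.  The
    default threshold is the signal's half depth — the midpoint of its
    robust (2nd/98th-percentile) range, which marks trough edges at the
    midpoint of the rise and fall — capped at the mean (z = 0) so that
    spiky burst trains with rare tall peaks do not merge adjacent troughs;
    pass an explicit z-level to override (0.0 thresholds at the mean).
    Raises NoOscillationError when no complete trough exists.
    """
    z = _normalized(series, window)
    if threshold is None:
        lo_z, hi_z = np.percentile(z, [2.0, 98.0])
        threshold = min(0.5 * (lo_z + hi_z), 0.0)
    intervals = _crossings(z, series.t, threshold)
    if not intervals:
        raise NoOscillationError("no complete trough in series: lag undefined")
    lag = float(np.mean([b - a for a, b in intervals]))
    return WaveMetrics(
        period=metrics.period,
        lag_time=lag,
        growth_time=metrics.period - lag,
        dominant_frequency=metrics.dominant_frequency,
    )


def number_density(tracks: pd.DataFrame, cell_volume: float) -> float:
    """Time-averaged droplet count per unit cell volume (µm⁻³)."""
    if cell_volume <= 0:
        raise ValueError("cell volume must be > 0")
    if tracks.empty:
        return 0.0
    counts = tracks.groupby("t").size()
    return float(counts.mean() / cell_volume)
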