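"""Near-real-time piecewise-linear trend segmentation of energy trajectories.

The monitoring layer assumes the energy signal consists of noisy segments
whose linear trend is stable within a segment and shifts abruptly at
changepoints.  The default engine is an exact dynamic-programming optimal
partitioning over a uniform grid: each segment is fit by ordinary least
squares and changepoints minimise the total squared residual plus a
BIC-type penalty per changepoint, subject to a minimum segment length.
A Bayesian changepoint engine could be substituted behind the same
interface; the contract is only "abrupt trend changes + per-segment linear
fit".

Sign convention: a negative trend means the energy is decreasing, i.e. the
assembly is progressing.  Trends are in k_BT per second of simulated time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "UniformSeries",
    "Segment",
    "SegmentationConfig",
    "LatestTrend",
    "resample_uniform",
    "segment_series",
    "latest_trend",
]


class InsufficientDataError(ValueError):
    """Fewer samples than the operation can work with."""


@dataclass(frozen=True)
class UniformSeries:
    """Values on a uniform time grid covering [times[0], times[-1]]."""

    times: np.ndarray
    values: np.ndarray

    @property
    def n_grid(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class Segment:
    """One trend segment with its stochastic coordinates.

    trend : OLS slope of the values over the segment (k_BT / s)
    mean, std : plain moments of the values within the segment (k_BT)
    dwell : t_end - t_start (s), the dwelling time in the macrostate
    """

    t_start: float
    t_end: float
    trend: float
    mean: float
    std: float
    i_start: int = 0
    i_end: int = 0

    @property
    def dwell(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the segmentation engine.

    n_grid : points of the uniform grid one analysed window is resampled to.
    min_segment_length : shortest admissible segment, in grid points.
    penalty : cost per changepoint; ``None`` selects a BIC-type default
        ``penalty_scale * sigma^2 * ln(n)`` with sigma estimated robustly
        from second differences (so a noiseless signal gets an almost-free
        penalty and is segmented exactly).
    """

    n_grid: int = 1000
    min_segment_length: int = 10
    penalty: Optional[float] = None
    penalty_scale: float = 3.0
    min_window_samples: int = 8


def resample_uniform(
    times: np.ndarray, values: np.ndarray, n_grid: int
) -> UniformSeries:
    """Linear interpolation onto ``n_grid`` equally spaced points.

    Endpoints are preserved exactly.  Requires >= 2 strictly increasing
    sample times.
    """
    times = np.asarray(times, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if len(times) < 2:
        raise InsufficientDataError("need at least 2 samples to resample")
    if np.any(np.diff(times) <= 0):
        raise ValueError("sample times must be strictly increasing")
    if n_grid < 2:
        raise ValueError("n_grid must be at least 2")
    grid = np.linspace(times[0], times[-1], n_grid)
    vals = np.interp(grid, times, values)
    vals[0] = values[0]
    vals[-1] = values[-1]
    return UniformSeries(times=grid, values=vals)


def _noise_scale(y: np.ndarray) -> float:
    """Robust noise sigma from second differences (trend-insensitive)."""
    if len(y) < 3:
        return 0.0
    d2 = np.diff(y, n=2)
    mad = np.median(np.abs(d2 - np.median(d2)))
    return float(1.4826 * mad / np.sqrt(6.0))


def _optimal_breakpoints(
    y: np.ndarray, min_len: int, penalty: float
) -> list[int]:
    """DP optimal partitioning with per-segment OLS-line costs.

    Returns interior breakpoints (grid indices) of the optimal partition of
    ``y`` minimising  sum SSE(segment) + penalty * (#segments - 1).
    """
    n = len(y)
    x = np.arange(n, dtype=np.float64)
    z0 = np.zeros(1)
    sx = np.concatenate([z0, np.cumsum(x)])
    sy = np.concatenate([z0, np.cumsum(y)])
    sxx = np.concatenate([z0, np.cumsum(x * x)])
    sxy = np.concatenate([z0, np.cumsum(x * y)])
    syy = np.concatenate([z0, np.cumsum(y * y)])

    cost = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=np.int64)
    cost[0] = 0.0
    for j in range(min_len, n + 1):
        i = np.arange(0, j - min_len + 1)
        m = (j - i).astype(np.float64)
        dx = sx[j] - sx[i]
        dy = sy[j] - sy[i]
        dxx = (sxx[j] - sxx[i]) - dx * dx / m
        dxy = (sxy[j] - sxy[i]) - dx * dy / m
        dyy = (syy[j] - syy[i]) - dy * dy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            sse = dyy - np.where(dxx > 0, dxy * dxy / np.where(dxx > 0, dxx, 1.0), 0.0)
        sse = np.maximum(sse, 0.0)
        cand = cost[i] + sse + np.where(i > 0, penalty, 0.0)
        k = int(np.argmin(cand))
        cost[j] = cand[k]
        prev[j] = i[k]
    bps: list[int] = []
    j = n
    while j > 0:
        i = int(prev[j])
        if i > 0:
            bps.append(i)
        j = i
    return bps[::-1]


def _fit_segment(t: np.ndarray, y: np.ndarray, i0: int, i1: int) -> Segment:
    ts = t[i0:i1]
    ys = y[i0:i1]
    if len(ys) >= 2 and ts[-1] > ts[0]:
        slope = float(np.polyfit(ts, ys, 1)[0])
    else:
        slope = 0.0
    return Segment(
        t_start=float(ts[0]),
        t_end=float(t[i1] if i1 < len(t) else ts[-1]),
        trend=slope,
        mean=float(ys.mean()),
        std=float(ys.std()),
        i_start=i0,
        i_end=i1,
    )


def segment_series(
    series: UniformSeries, config: SegmentationConfig = SegmentationConfig()
) -> list[Segment]:
    """Partition a uniform series into contiguous linear-trend segments.

    Segments are returned in time order; their union covers the window
    exactly (each segment ends where the next begins, the last one at the
    final grid time).  If the series is shorter than two minimum segment
    lengths a single-segment fit is returned with a warning.
    """
    y = series.values
    t = series.times
    n = len(y)
    min_len = max(2, config.min_segment_length)
    if n < 2 * min_len:
        warnings.warn(
            "window shorter than two minimum segment lengths; "
            "falling back to a single-segment fit"
        )
        return [_fit_segment(t, y, 0, n)]
    penalty = config.penalty
    if penalty is None:
        sigma2 = _noise_scale(y) ** 2
        scale_floor = 1e-12 * (1.0 + float(np.var(y)))
        penalty = max(config.penalty_scale * sigma2 * np.log(n), scale_floor)
    bps = _optimal_breakpoints(y, min_len, penalty)
    bounds = [0, *bps, n]
    return [
        _fit_segment(t, y, bounds[k], bounds[k + 1])
        for k in range(len(bounds) - 1)
    ]


@dataclass(frozen=True)
class LatestTrend:
    """Result of one monitoring epoch: the open segment and its trend t*."""

    segment: Segment
    t_star: float
    new_changepoints: tuple  # absolute times of confirmed changepoints
    segments: tuple          # all segments of the analysed window


def latest_trend(
    times: np.ndarray,
    values: np.ndarray,
    last_changepoint_time: float,
    t_now: float,
    config: SegmentationConfig = SegmentationConfig(),
) -> Optional[LatestTrend]:
    """Segment the partial window [last changepoint, now]; return the final
    segment and its trend t*.

    The window spans from the last detected changepoint (or the start of
    the run) to the current time.  Returns ``None`` (a no-decision
    sentinel, treated as "not trapped") when the window holds too few
    samples or no time span.  Deterministic: repeated calls with unchanged
    data give identical output.
    """
    times = np.asarray(times, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if t_now <= last_changepoint_time:
        raise ValueError("t_now must exceed the last changepoint time")
    mask = (times >= last_changepoint_time) & (times <= t_now)
    t_w = times[mask]
    y_w = values[mask]
    if len(t_w) < max(2, config.min_window_samples) or t_w[-1] <= t_w[0]:
        return None
    n_grid = min(config.n_grid, max(len(t_w), 2 * config.min_segment_length))
    series = resample_uniform(t_w, y_w, n_grid)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        segs = segment_series(series, config)
    last = segs[-1]
    new_cps = tuple(s.t_start for s in segs[1:])
    return LatestTrend(
        segment=last, t_star=last.trend, new_changepoints=new_cps,
        segments=tuple(segs),
    )
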