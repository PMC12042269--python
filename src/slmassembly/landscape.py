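"""Learning phase: monitoring-interval calibration, segment ensembles, the
dwelling-time-vs-trend stochastic landscape, and the trap region T*.

Kinetic traps are long-lived metastable macrostates with near-zero energy
trend.  Pooling the segments of an equilibrium trajectory ensemble, the
trap region T* = [-tau, +tau] is the narrowest symmetric trend interval
around zero that contains 20-21% of the segments; during the activation
phase a trend inside T* triggers a shock.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .segmentation import (
    Segment,
    SegmentationConfig,
    latest_trend,
    resample_uniform,
    segment_series,
)

__all__ = [
    "SegmentEnsemble",
    "TrapRegion",
    "StochasticLandscape",
    "LearnedControl",
    "calibrate_w2",
    "find_trap_region",
    "build_landscape",
    "collect_segments_online",
]


@dataclass
class SegmentEnsemble:
    """Pooled segments from an ensemble of equilibrium runs at fixed J_s."""

    segments: list
    realization: np.ndarray  # realization tag per segment

    def __post_init__(self) -> None:
        self.realization = np.asarray(self.realization, dtype=np.int64)
        if len(self.realization) != len(self.segments):
            raise ValueError("one realization tag per segment required")
        if len(self.segments) == 0:
            raise ValueError("empty segment ensemble")
        if not np.all(np.isfinite(self.trends)):
            raise ValueError("non-finite trend in segment ensemble")

    @property
    def trends(self) -> np.ndarray:
        return np.array([s.trend for s in self.segments])

    @property
    def dwells(self) -> np.ndarray:
        return np.array([s.dwell for s in self.segments])

    def __len__(self) -> int:
        return len(self.segments)


def calibrate_w2(equilibrium_tfas_values: Sequence[float]) -> float:
    """Monitoring interval W2 = 0.01 x median(T_FAS) (s).

    Unassembled realizations contribute their total simulated time as
    T_FAS.  For even-length input the median is the mean of the central
    pair (numpy convention).
    """
    vals = np.asarray(list(equilibrium_tfas_values), dtype=np.float64)
    if len(vals) == 0:
        raise ValueError("empty T_FAS collection")
    return 0.01 * float(np.median(vals))


@dataclass(frozen=True)
class TrapRegion:
    """Symmetric trend interval T* = [-tau, +tau] that triggers shocks."""

    tau: float
    achieved_fraction: float
    band_attained: bool = True
    n_segments: int = 0

    def __contains__(self, trend: float) -> bool:
        return bool(abs(trend) <= self.tau)


def find_trap_region(
    trends: Sequence[float] | SegmentEnsemble,
    lo: float = 0.20,
    hi: float = 0.21,
) -> TrapRegion:
    """Smallest tau with fraction of |trend| <= tau inside [lo, hi].

    Implemented as a bisection over the order statistics of |trend| (the
    inclusion fraction is a step function of tau, so this solves the
    binary-search target exactly).  When ties make the band unattainable
    the tau minimising |fraction - (lo+hi)/2| is returned flagged.
    """
    if isinstance(trends, SegmentEnsemble):
        trends = trends.trends
    t = np.sort(np.abs(np.asarray(list(trends), dtype=np.float64)))
    n = len(t)
    if n == 0:
        raise ValueError("empty trend ensemble")
    if n < 50:
        warnings.warn(f"trap-region training ensemble has only {n} segments")

    def fraction(tau: float) -> float:
        return float(np.searchsorted(t, tau, side="right")) / n

    k0 = int(np.ceil(lo * n))
    for k in range(max(k0, 1), n + 1):
        tau = float(t[k - 1])
        frac = fraction(tau)
        if lo <= frac <= hi:
            return TrapRegion(tau, frac, True, n)
        if frac > hi:
            break
    # ties / atoms make the band unattainable
    candidates = np.unique(np.concatenate([[0.0], t]))
    fracs = np.array([fraction(c) for c in candidates])
    k = int(np.argmin(np.abs(fracs - 0.5 * (lo + hi))))
    return TrapRegion(float(candidates[k]), float(fracs[k]), False, n)


@dataclass
class StochasticLandscape:
    """Binned map trend -> expected dwelling time, with the raw scatter."""

    bin_centers: np.ndarray
    bin_means: np.ndarray
    trends: np.ndarray
    dwells: np.ndarray

    def query(self, trend) -> np.ndarray | float:
        """Expected dwelling time at a trend value (piecewise linear)."""
        valid = np.isfinite(self.bin_means)
        if valid.sum() == 0:
            raise ValueError("landscape has no populated bins")
        if valid.sum() == 1:
            const = float(self.bin_means[valid][0])
            out = np.full_like(np.asarray(trend, dtype=float), const)
            return float(out) if np.isscalar(trend) else out
        res = np.interp(
            trend, self.bin_centers[valid], self.bin_means[valid]
        )
        return float(res) if np.isscalar(trend) else res


def build_landscape(
    ensemble: SegmentEnsemble | tuple, n_bins: int = 21
) -> StochasticLandscape:
    """Bin mean dwelling time over trend; interpolate between bin centers.

    The landscape is diagnostic — the controller itself only needs T* —
    but it is the place to see kinetic traps: dwelling times rise sharply
    as the trend approaches zero.
    """
    if isinstance(ensemble, SegmentEnsemble):
        trends, dwells = ensemble.trends, ensemble.dwells
    else:
        trends, dwells = (np.asarray(x, dtype=np.float64) for x in ensemble)
    if len(trends) == 0:
        raise ValueError("empty ensemble")
    lo, hi = float(trends.min()), float(trends.max())
    if lo == hi:
        centers = np.array([lo])
        means = np.array([float(dwells.mean())])
        return StochasticLandscape(centers, means, trends, dwells)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(trends, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            means[b] = float(dwells[sel].mean())
    centers = 0.5 * (edges[:-1] + edges[1:])
    return StochasticLandscape(centers, means, trends, dwells)


def collect_segments_online(
    times: np.ndarray,
    energies: np.ndarray,
    w2: float,
    config: SegmentationConfig = SegmentationConfig(),
) -> list[Segment]:
    """Replay the near-real-time monitoring protocol over a recorded run.

    Every ``w2`` seconds the partial window from the last confirmed
    changepoint to the epoch time is resampled, segmented, and any interior
    changepoints are confirmed; their segments are committed.  The window
    remaining after the final epoch is segmented once more so the committed
    segments cover the whole trajectory.
    """
    times = np.asarray(times, dtype=np.float64)
    energies = np.asarray(energies, dtype=np.float64)
    if w2 <= 0:
        raise ValueError("w2 must be positive")
    t_end = float(times[-1])
    committed: list[Segment] = []
    last_cp = float(times[0])
    epoch = np.floor(times[0] / w2) * w2 + w2
    while epoch < t_end:
        res = latest_trend(times, energies, last_cp, epoch, config)
        if res is not None and res.segments[:-1]:
            committed.extend(res.segments[:-1])
            last_cp = res.segments[-1].t_start
        epoch += w2
    res = latest_trend(times, energies, last_cp, t_end, config)
    if res is not None:
        committed.extend(res.segments)
    return committed


@dataclass
class LearnedControl:
    """Persisted artifacts of the learning phase for one J_s."""

    j_strong: float
    w2: float
    trap_region: TrapRegion
    n_trajectories: int = 0
    n_segments: int = 0
    seeds: tuple = ()
    landscape: Optional[StochasticLandscape] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "j_strong": self.j_strong,
                "w2": self.w2,
                "tau": self.trap_region.tau,
                "achieved_fraction": self.trap_region.achieved_fraction,
                "band_attained": self.trap_region.band_attained,
                "n_trajectories": self.n_trajectories,
                "n_segments": self.n_segments,
                "seeds": list(self.seeds),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LearnedControl":
        obj = json.loads(text)
        return cls(
            j_strong=obj["j_strong"],
            w2=obj["w2"],
            trap_region=TrapRegion(
                tau=obj["tau"],
                achieved_fraction=obj["achieved_fraction"],
                band_attained=obj["band_attained"],
                n_segments=obj.get("n_segments", 0),
            ),
            n_trajectories=obj.get("n_trajectories", 0),
            n_segments=obj.get("n_segments", 0),
            seeds=tuple(obj.get("seeds", ())),
        )
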