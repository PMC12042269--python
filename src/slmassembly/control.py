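"""Closed-loop drive: monitor the latest energy trend every W2 seconds and
apply transient interaction-energy shocks when the system looks trapped.

A shock divides both interaction energies by the drive amplitude rho >= 1
for a duration W1 (mimicking a global, pH-like weakening of all bonds),
after which the equilibrium energies are restored; a relaxation gap then
suspends further triggering so the system can settle into a new metastable
state.  rho = 1 leaves the dynamics untouched: the controlled run is then
bit-identical to the equilibrium run with the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

from .engine import RateLaw, Simulation, Trajectory
from .landscape import LearnedControl, TrapRegion
from .model import ConfigurationError, InteractionParams, LatticeState, TargetSet
from .segmentation import SegmentationConfig, latest_trend

__all__ = [
    "ControlConfig",
    "ScheduleState",
    "ShockEvent",
    "ControlledTrajectory",
    "shock_params",
    "control_step",
    "run_controlled",
]


def shock_params(params: InteractionParams, rho: float) -> InteractionParams:
    """Interaction energies during a shock: J_s/rho and J_w/rho, r0 unchanged."""
    if rho < 1.0:
        raise ConfigurationError(f"drive amplitude must be >= 1, got {rho}")
    return replace(params, j_strong=params.j_strong / rho, j_weak=params.j_weak / rho)


@dataclass
class ControlConfig:
    """Drive parameters: amplitude rho, shock duration W1, monitoring
    interval W2, post-shock relaxation gap, and the learned trap region.

    Defaults (when not given): W1 = W2/2 — inside the stated bound
    W1 < 0.01 x median(T_FAS) since W2 equals that bound — and
    relaxation_gap = W2.
    """

    rho: float
    w2: float
    trap_region: TrapRegion
    w1: Optional[float] = None
    relaxation_gap: Optional[float] = None
    seg_config: SegmentationConfig = field(default_factory=SegmentationConfig)
    mask_shocks: bool = False

    def __post_init__(self) -> None:
        if self.w1 is None:
            self.w1 = 0.5 * self.w2
        if self.relaxation_gap is None:
            self.relaxation_gap = self.w2
        if self.rho < 1.0:
            raise ConfigurationError("rho must be >= 1")
        if not (0.0 < self.w1 <= self.w2):
            raise ConfigurationError("need 0 < W1 <= W2")
        if self.relaxation_gap < 0.0:
            raise ConfigurationError("relaxation gap must be >= 0")

    @classmethod
    def from_learned(cls, learned: LearnedControl, rho: float, **kw) -> "ControlConfig":
        return cls(rho=rho, w2=learned.w2, trap_region=learned.trap_region, **kw)


@dataclass
class ScheduleState:
    """Mutable shock schedule bookkeeping carried between epochs."""

    shock_active: bool = False
    shock_end: float = math.inf
    last_shock_end: float = -math.inf


Action = Literal["none", "start_shock", "end_shock"]


def control_step(
    t_now: float,
    latest_t_star: Optional[float],
    config: ControlConfig,
    schedule: ScheduleState,
) -> Action:
    """Decide the drive action at an evaluation epoch or scheduled shock end.

    A shock starts iff the latest trend t* lies inside T* = [-tau, tau],
    no shock is active, and the relaxation gap since the previous shock has
    elapsed; it ends exactly W1 after it started.  ``latest_t_star = None``
    (no decision from the segmentation layer) never triggers.
    """
    if schedule.shock_active:
        return "end_shock" if t_now >= schedule.shock_end else "none"
    if latest_t_star is None:
        return "none"
    if latest_t_star not in config.trap_region:
        return "none"
    if t_now < schedule.last_shock_end + config.relaxation_gap:
        return "none"
    return "start_shock"


@dataclass(frozen=True)
class ShockEvent:
    """One drive activation: [t_on, t_off), the trend t* that triggered it,
    and the start of the triggering segment."""

    t_on: float
    t_off: float
    trigger_trend: float
    seg_start: float
    truncated: bool = False

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on


@dataclass
class ControlledTrajectory:
    """A trajectory plus its shock intervals."""

    trajectory: Trajectory
    shocks: list
    rho: float
    w1: float
    w2: float

    @property
    def n_shocks(self) -> int:
        return len(self.shocks)


def run_controlled(
    initial_state: LatticeState,
    params: InteractionParams,
    targets: TargetSet,
    config: ControlConfig,
    t_cap: int,
    seed: int,
    *,
    stop_on_assembly: bool = True,
    record_stride: Optional[int] = None,
    rate_law: RateLaw = "symmetric",
    distance_convention: str = "state_bonds",
    validate_every: int = 100_000,
    max_epochs: Optional[int] = None,
) -> ControlledTrajectory:
    """Run one closed-loop controlled trajectory of at most ``t_cap`` steps.

    The KMC loop is interrupted at every integer multiple of W2 to evaluate
    the latest segment trend t* over the window since the last confirmed
    changepoint, and at scheduled shock ends to restore the equilibrium
    energies.  Parameter switches happen at the first KMC event on or after
    the nominal boundary (events are discrete); recorded shock intervals
    carry the nominal [t_on, t_on + W1).

    Segmentation state (the last changepoint) persists across shocks, and
    shocked samples are part of the analysed window unless
    ``config.mask_shocks`` is set.
    """
    if record_stride is None:
        record_stride = max(1, int(t_cap) // 20_000)
    sim = Simulation(
        initial_state, params, targets, seed,
        rate_law=rate_law, record_stride=record_stride,
        distance_convention=distance_convention, validate_every=validate_every,
    )
    shocked = shock_params(params, config.rho)
    schedule = ScheduleState()
    shocks: list[ShockEvent] = []
    last_cp = 0.0
    w2 = config.w2
    next_epoch = w2
    n_epochs = 0

    while True:
        if schedule.shock_active and schedule.shock_end < next_epoch:
            t_stop = schedule.shock_end
        else:
            t_stop = next_epoch
        status = sim.advance(
            max_steps=t_cap, t_cap=t_cap, t_stop=t_stop,
            stop_on_assembly=stop_on_assembly,
        )
        if status in (sim._kernel.STATUS_TCAP, sim._kernel.STATUS_ASSEMBLED,
                      sim._kernel.STATUS_STALLED):
            break
        t_now = sim.time

        if schedule.shock_active and t_now >= schedule.shock_end:
            sim.set_params(params)
            sim.shock_active = False
            schedule.shock_active = False
            schedule.last_shock_end = schedule.shock_end
            schedule.shock_end = math.inf

        if t_now >= next_epoch:
            n_epochs += 1
            if max_epochs is not None and n_epochs > max_epochs:
                break
            times, energies, _, _, shock_flags = sim.records()
            if config.mask_shocks:
                keep = ~shock_flags
                times, energies = times[keep], energies[keep]
            res = latest_trend(times, energies, last_cp, t_now, config.seg_config)
            t_star = None
            seg_start = last_cp
            if res is not None:
                t_star = res.t_star
                seg_start = res.segment.t_start
                if res.new_changepoints:
                    last_cp = res.new_changepoints[-1]
            action = control_step(t_now, t_star, config, schedule)
            if action == "start_shock":
                sim.set_params(shocked)
                sim.shock_active = True
                schedule.shock_active = True
                schedule.shock_end = t_now + config.w1
                shocks.append(
                    ShockEvent(
                        t_on=t_now, t_off=t_now + config.w1,
                        trigger_trend=float(t_star), seg_start=seg_start,
                    )
                )
            next_epoch = w2 * (math.floor(t_now / w2) + 1)

    # restore params and mark a shock truncated by the step cap
    if schedule.shock_active:
        sim.set_params(params)
        sim.shock_active = False
        if shocks and sim.time < shocks[-1].t_off:
            last = shocks[-1]
            shocks[-1] = ShockEvent(
                t_on=last.t_on, t_off=sim.time,
                trigger_trend=last.trigger_trend, seg_start=last.seg_start,
                truncated=True,
            )
    return ControlledTrajectory(
        trajectory=sim.trajectory(), shocks=shocks,
        rho=config.rho, w1=float(config.w1), w2=float(config.w2),
    )
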