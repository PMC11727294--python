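"""Adaptive resuscitation controller (ARC).

The ARC regulates MAP by estimating the subject's volume responsiveness
on-line.  A 100-mL bolus over the first minute seeds a pressure-volume
history; an ordinary-least-squares regression of observed MAP on cumulative
infused volume gives the local responsiveness dP/dV, and the commanded
infusion rate is the one that would raise pressure at a fixed resuscitation
pace:

    rate (dV/dT) = pace (dP/dT) / slope (dP/dV)

re-fitted at every 15-s control tick so the controller adapts as
responsiveness changes.  Safety logic floors the slope (avoiding rate
blow-up on flat responses), caps the rate, and cuts the rate to zero once
the target MAP is reached, re-engaging with a small hysteresis when
pressure sags below target again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .trace import InfusionCommand, ValidationError


@dataclass
class ARCParams:
    target: float = 65.0  # mmHg
    pace: float = 6.0  # mmHg/min resuscitation pace (dP/dT)
    window: int = 5  # regression window, most recent (V, P) points
    slope_floor: float = 0.01  # mmHg/mL safety floor on the fitted slope
    rate_cap: float = 250.0  # mL/min
    bolus_volume: float = 100.0  # mL over the first minute
    bolus_duration: float = 60.0  # s
    control_period: float = 15.0  # s
    hysteresis: float = 1.0  # mmHg below target before re-engaging

    def validate(self) -> None:
        if self.target <= 0 or self.pace <= 0 or self.rate_cap <= 0:
            raise ValidationError("target, pace and rate_cap must be > 0")
        if self.window < 2:
            raise ValidationError("window must be >= 2")


def fit_pv_slope(history: list[tuple[float, float]], window: int = 5) -> float:
    """OLS slope of pressure on cumulative volume over the recent window.

    Raises ValueError when the window contains no volume variation
    (the slope is unidentifiable); callers apply the safety floor instead.
    """
    pts = history[-window:]
    if len(pts) < 2:
        raise ValueError("need at least 2 history points")
    v = np.array([p[0] for p in pts])
    p = np.array([p[1] for p in pts])
    if np.ptp(v) == 0:
        raise ValueError("all volumes identical; slope unidentifiable")
    return float(np.polyfit(v, p, 1)[0])


def rate_from_slope(
    slope: float, pace: float = 6.0, floor: float = 0.01, cap: float = 250.0
) -> float:
    """Infusion rate dV/dT = pace / slope with safety floor and cap."""
    if pace <= 0:
        raise ValidationError("pace must be > 0")
    eff = max(slope, floor)
    return float(np.clip(pace / eff, 0.0, cap))


@dataclass
class ARCState:
    phase: str = "bolus"  # "bolus" | "adaptive" | "at_target"
    history: list = field(default_factory=list)  # (cumulative V mL, MAP mmHg)
    slope: Optional[float] = None
    rate: float = 0.0  # last commanded rate, mL/min
    cumulative_volume: float = 0.0  # commanded volume so far, mL
    last_time: Optional[float] = None


class AdaptiveController:
    """Tick-driven ARC; call :meth:`step` once per control period."""

    name = "ARC"

    def __init__(self, params: Optional[ARCParams] = None):
        self.params = params or ARCParams()
        self.params.validate()
        self.state = ARCState()

    def _record(self, map_estimate: float) -> None:
        # Only volume-advancing observations enter the P-V history: points
        # taken while the pump is off carry no slope information and would
        # make the windowed regression singular.
        s = self.state
        if not s.history or s.cumulative_volume > s.history[-1][0] + 1e-9:
            s.history.append((s.cumulative_volume, map_estimate))

    def step(self, map_estimate: float, t: float) -> InfusionCommand:
        p, s = self.params, self.state

        # integrate the previous command into the volume ledger
        if s.last_time is not None:
            s.cumulative_volume += s.rate * (t - s.last_time) / 60.0
        s.last_time = t

        if map_estimate is None or not math.isfinite(map_estimate):
            # hold the previous rate on a bad sample
            return InfusionCommand(time=t, rate_ml_min=s.rate, fluid="WB")

        if t < p.bolus_duration:
            s.phase = "bolus"
            self._record(map_estimate)
            s.rate = p.bolus_volume / p.bolus_duration * 60.0
            return InfusionCommand(time=t, rate_ml_min=s.rate, fluid="WB")

        self._record(map_estimate)

        at_target = map_estimate >= p.target or (
            s.phase == "at_target" and map_estimate >= p.target - p.hysteresis
        )
        if at_target:
            s.phase = "at_target"
            s.rate = 0.0
            return InfusionCommand(time=t, rate_ml_min=0.0, fluid="WB")

        s.phase = "adaptive"
        # refit on every iteration over the recent window
        try:
            s.slope = fit_pv_slope(s.history, p.window)
        except ValueError:
            s.slope = None
        eff_slope = s.slope if s.slope is not None else 0.0
        s.rate = rate_from_slope(eff_slope, p.pace, p.slope_floor, p.rate_cap)
        return InfusionCommand(time=t, rate_ml_min=s.rate, fluid="WB")


def arc_step(
    controller: AdaptiveController, map_estimate: float, t: float
) -> tuple[InfusionCommand, ARCState]:
    """Functional wrapper: one control tick -> (command, controller state)."""
    cmd = controller.step(map_estimate, t)
    return cmd, controller.state
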