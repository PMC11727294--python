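"""Automated stepwise hemorrhage controller ("AutoBleed").

Drives the subject down a ladder of MAP step targets (default 75, 65, 55,
45, 35 mmHg), withdrawing blood when above the current target and
reinfusing banked blood when below it, holding each step for a fixed time
before descending.  Withdrawn whole blood is mixed with CPDA-1
anticoagulant at 1 part per 7 parts blood.  The bottom step (35 mmHg) is
maintained until either the maximum hold elapses or arterial lactate
crosses the shock threshold (>= 4 mmol/L), which terminates the hemorrhage
phase.  The first step is the highest ladder target strictly below the
subject's post-stabilization baseline.

The original decision-table software is unpublished; this proportional
step controller reproduces its observable input-output behavior (step
descent, holds, withdraw/reinfuse regulation, termination rules).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .subject import SubjectState, draw_blood
from .trace import ValidationError


@dataclass
class HemorrhageProtocol:
    """Stepwise hemorrhage schedule and termination rules."""

    step_targets: tuple[float, ...] = (75.0, 65.0, 55.0, 45.0, 35.0)
    hold_min: float = 10.0  # per-step hold, minutes
    bottom_hold_max_min: float = 90.0  # maximum bottom-step hold, minutes
    bottom_hold_min_min: float = 10.0  # minimum bottom-step hold, minutes
    lactate_threshold: float = 4.0  # mmol/L, terminates the bottom hold
    cpda_ratio: float = 7.0  # 1 part CPDA-1 per this many parts blood
    kp: float = 40.0  # proportional gain, mL/min per mmHg
    max_pump_rate: float = 100.0  # mL/min withdraw/reinfuse cap
    settle_band: float = 2.0  # mmHg: at-target band that starts the hold timer
    deadband: float = 1.0  # mmHg: no pumping inside this error band

    def validate(self) -> None:
        if any(b >= a for a, b in zip(self.step_targets, self.step_targets[1:])):
            raise ValidationError("step_targets must be strictly decreasing")
        if min(self.hold_min, self.bottom_hold_max_min, self.lactate_threshold) <= 0:
            raise ValidationError("protocol thresholds must be > 0")


class AutoBleed:
    """Stateful stepwise hemorrhage controller.

    Call :meth:`command` once per simulation step; apply the returned rate
    to the plant (positive = withdraw, negative = reinfuse banked blood).
    ``done`` flips when the bottom-hold termination rule fires.
    """

    def __init__(self, protocol: HemorrhageProtocol, baseline_map: float):
        protocol.validate()
        self.protocol = protocol
        self.steps = [s for s in protocol.step_targets if s < baseline_map]
        if not self.steps:
            raise ValidationError(
                f"no hemorrhage step lies below baseline {baseline_map:.1f} mmHg"
            )
        self.idx = 0
        self.phase = "approach"  # "approach" | "hold"
        self.hold_elapsed = 0.0  # s within the current hold
        self.done = False
        self.bottom_hold_started: Optional[float] = None

    @property
    def current_target(self) -> float:
        return self.steps[self.idx]

    @property
    def at_bottom(self) -> bool:
        return self.idx == len(self.steps) - 1

    def command(self, state: SubjectState, t: float, dt: float) -> float:
        """Pump rate for this step (mL/min; >0 withdraw, <0 reinfuse)."""
        if self.done:
            return 0.0
        p = self.protocol
        err = state.map_now - self.current_target
        if abs(err) <= p.deadband:
            err = 0.0
        rate = max(-p.max_pump_rate, min(p.max_pump_rate, p.kp * err))
        if rate < 0 and state.blood_bank_ml <= 0:
            rate = 0.0  # nothing banked to give back

        if self.phase == "approach":
            if abs(err) <= p.settle_band:
                self.phase = "hold"
                self.hold_elapsed = 0.0
                if self.at_bottom:
                    self.bottom_hold_started = t
        else:
            self.hold_elapsed += dt
            if self.at_bottom:
                held_min = self.hold_elapsed / 60.0
                if held_min >= p.bottom_hold_max_min or (
                    held_min >= p.bottom_hold_min_min
                    and state.lactate >= p.lactate_threshold
                ):
                    self.done = True
                    return 0.0
            elif self.hold_elapsed >= p.hold_min * 60.0:
                self.idx += 1
                self.phase = "approach"
        return rate

    def apply(self, state: SubjectState, rate: float, dt: float) -> None:
        """Ledger updates for one dt of the commanded rate."""
        vol = abs(rate) * dt / 60.0
        if rate > 0:
            draw_blood(state, vol, cpda_ratio=self.protocol.cpda_ratio)
        elif rate < 0:
            state.reservoirs["wb_reinfused"] += vol


def autobleed_step(
    controller: AutoBleed, state: SubjectState, t: float, dt: float = 1.0
) -> tuple[float, float]:
    """One AutoBleed decision: (signed pump rate mL/min, CPDA added mL).

    Convenience wrapper pairing :meth:`AutoBleed.command` with the CPDA
    bookkeeping for this step.
    """
    cpda_before = state.reservoirs["cpda"]
    rate = controller.command(state, t, dt)
    controller.apply(state, rate, dt)
    return rate, state.reservoirs["cpda"] - cpda_before
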