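"""Dual-input fuzzy-logic (DFL) resuscitation controller.

A zero-order Sugeno fuzzy inference system with two inputs and one output:

* ``PerformanceError`` (PE) — the ratio of current MAP to the target,
  partitioned into four sets (VeryLow, Low, NearSet, Set);
* ``d/dt PerformanceError`` (dPE) — the average rate of change of PE over
  the three most recent samples, in ratio per minute, partitioned into five
  sets (dropFast, dropSlow, noChange, riseSlow, riseFast).

Each of the 20 antecedent pairs maps to a constant output level in
{Off, MedLow, Med, MedHigh, High} = {0, 0.25, 0.5, 0.75, 1.0}; rule firing
strength is the product of the two antecedent memberships and the
defuzzified output is the strength-weighted average, scaled by the maximum
infusion rate (250 mL/min).  Off and High therefore correspond to 0 and
250 mL/min.

When fed by the intermittent-NIBP upsampler the controller starts every
resuscitation with a 100-mL bolus over the first minute (giving the
upsampler time to accumulate two readings); the flag is configurable off.

The membership breakpoints and rule table shipped here are reconstructions
of the qualitative control surface (more fluid when pressure is low and
dropping, none at or above target); both are fully configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .trace import InfusionCommand, ValidationError

INF = float("inf")

OUTPUT_LEVELS = {"Off": 0.0, "MedLow": 0.25, "Med": 0.5, "MedHigh": 0.75, "High": 1.0}

PE_LABELS = ("VeryLow", "Low", "NearSet", "Set")
DPE_LABELS = ("dropFast", "dropSlow", "noChange", "riseSlow", "riseFast")


def trapmf(x: float, a: float, b: float, c: float, d: float) -> float:
    """Trapezoidal membership; a<=b<=c<=d, +-inf shoulders allowed.

    A triangle is the degenerate case b == c.
    """
    if x < a or x > d:
        return 0.0
    if b <= x <= c:
        return 1.0
    if x < b:
        return (x - a) / (b - a)
    return (d - x) / (d - c)


@dataclass
class FuzzyPartition:
    """Piecewise-linear input partitions for PE and dPE.

    Each set is a trapezoid (a, b, c, d); triangles have b == c.  Defaults
    cover the whole operating range (max membership > 0 everywhere).
    """

    pe_sets: dict = field(
        default_factory=lambda: {
            "VeryLow": (-INF, -INF, 0.55, 0.70),
            "Low": (0.55, 0.75, 0.75, 0.90),
            "NearSet": (0.82, 0.93, 0.93, 1.00),
            "Set": (0.95, 1.00, INF, INF),
        }
    )
    dpe_sets: dict = field(
        default_factory=lambda: {
            "dropFast": (-INF, -INF, -0.25, -0.05),
            "dropSlow": (-0.25, -0.05, -0.05, 0.0),
            "noChange": (-0.05, 0.0, 0.0, 0.05),
            "riseSlow": (0.0, 0.05, 0.05, 0.25),
            "riseFast": (0.05, 0.25, INF, INF),
        }
    )

    def validate(self) -> None:
        if set(self.pe_sets) != set(PE_LABELS):
            raise ValidationError("pe_sets must carry exactly the 4 PE labels")
        if set(self.dpe_sets) != set(DPE_LABELS):
            raise ValidationError("dpe_sets must carry exactly the 5 dPE labels")

    def pe_memberships(self, pe: float) -> dict:
        return {k: trapmf(pe, *v) for k, v in self.pe_sets.items()}

    def dpe_memberships(self, dpe: float) -> dict:
        return {k: trapmf(dpe, *v) for k, v in self.dpe_sets.items()}


@dataclass
class RuleBase:
    """20-rule antecedent -> constant-consequent map plus the rate scale."""

    rules: dict = field(
        default_factory=lambda: {
            # (PE label, dPE label): output level
            **{("Set", d): "Off" for d in DPE_LABELS},
            ("NearSet", "dropFast"): "Med",
            ("NearSet", "dropSlow"): "MedLow",
            ("NearSet", "noChange"): "MedLow",
            ("NearSet", "riseSlow"): "Off",
            ("NearSet", "riseFast"): "Off",
            ("Low", "dropFast"): "High",
            ("Low", "dropSlow"): "MedHigh",
            ("Low", "noChange"): "MedHigh",
            ("Low", "riseSlow"): "Med",
            ("Low", "riseFast"): "MedLow",
            ("VeryLow", "dropFast"): "High",
            ("VeryLow", "dropSlow"): "High",
            ("VeryLow", "noChange"): "High",
            ("VeryLow", "riseSlow"): "MedHigh",
            ("VeryLow", "riseFast"): "Med",
        }
    )
    max_rate: float = 250.0  # mL/min; High corresponds to this rate

    def validate(self) -> None:
        expected = {(p, d) for p in PE_LABELS for d in DPE_LABELS}
        if set(self.rules) != expected:
            raise ValidationError("rule base must cover all 20 antecedent pairs")
        bad = [lvl for lvl in self.rules.values() if lvl not in OUTPUT_LEVELS]
        if bad:
            raise ValidationError(f"unknown output level(s): {bad}")
        if any(self.rules[("Set", d)] != "Off" for d in DPE_LABELS):
            raise ValidationError("at-target (Set) rules must be Off")


def sugeno_infer(
    pe: float,
    dpe: float,
    partition: Optional[FuzzyPartition] = None,
    rules: Optional[RuleBase] = None,
) -> tuple[float, float]:
    """Zero-order Sugeno inference: (fraction in [0,1], rate in mL/min)."""
    partition = partition or FuzzyPartition()
    rules = rules or RuleBase()
    if not (math.isfinite(pe) and math.isfinite(dpe)):
        raise ValidationError("inputs must be finite")
    mu_pe = partition.pe_memberships(pe)
    mu_dpe = partition.dpe_memberships(dpe)
    num = den = 0.0
    for (pl, dl), level in rules.rules.items():
        w = mu_pe[pl] * mu_dpe[dl]
        if w > 0:
            num += w * OUTPUT_LEVELS[level]
            den += w
    if den == 0.0:
        raise ValidationError(
            f"no rule fires at PE={pe:.3f}, dPE={dpe:.3f}: partition coverage violated"
        )
    frac = num / den
    return frac, frac * rules.max_rate


@dataclass
class DFLState:
    pe_history: list = field(default_factory=list)  # (time s, PE), last 3 kept
    phase: str = "bolus"  # "bolus" | "fuzzy"
    rate: float = 0.0


def compute_inputs(
    map_estimate: float, target: float, state: DFLState, t: float
) -> tuple[float, float]:
    """PE = MAP/target; dPE/dt = mean slope over the 3 most recent PE values.

    dPE/dt is in ratio per minute.  With fewer than three points the
    available successive differences are used (zero with a single point).
    Appends the new PE to the state history.
    """
    if target <= 0:
        raise ValidationError("target must be > 0")
    if not math.isfinite(map_estimate):
        raise ValidationError("non-finite MAP estimate")
    pe = map_estimate / target
    state.pe_history.append((t, pe))
    if len(state.pe_history) > 3:
        state.pe_history.pop(0)
    pts = state.pe_history
    if len(pts) < 2:
        return pe, 0.0
    slopes = [
        (p1 - p0) / (t1 - t0) * 60.0
        for (t0, p0), (t1, p1) in zip(pts, pts[1:])
        if t1 > t0
    ]
    dpe = float(np.mean(slopes)) if slopes else 0.0
    return pe, dpe


class FuzzyController:
    """Tick-driven DFL; call :meth:`step` once per control period."""

    name = "DFL"

    def __init__(
        self,
        target: float = 65.0,
        partition: Optional[FuzzyPartition] = None,
        rules: Optional[RuleBase] = None,
        bolus_enabled: bool = True,
        bolus_volume: float = 100.0,
        bolus_duration: float = 60.0,
    ):
        if target <= 0:
            raise ValidationError("target must be > 0")
        self.target = target
        self.partition = partition or FuzzyPartition()
        self.rules = rules or RuleBase()
        self.partition.validate()
        self.rules.validate()
        self.bolus_enabled = bolus_enabled
        self.bolus_volume = bolus_volume
        self.bolus_duration = bolus_duration
        self.state = DFLState()

    def step(self, map_estimate: float, t: float) -> InfusionCommand:
        s = self.state
        if map_estimate is None or not math.isfinite(map_estimate):
            return InfusionCommand(time=t, rate_ml_min=s.rate, fluid="WB")
        # PE history tracks every tick, including during the bolus
        pe, dpe = compute_inputs(map_estimate, self.target, s, t)
        if self.bolus_enabled and t < self.bolus_duration:
            s.phase = "bolus"
            s.rate = self.bolus_volume / self.bolus_duration * 60.0
        else:
            s.phase = "fuzzy"
            _, s.rate = sugeno_infer(pe, dpe, self.partition, self.rules)
        return InfusionCommand(time=t, rate_ml_min=s.rate, fluid="WB")


def dfl_step(
    controller: FuzzyController, map_estimate: float, t: float
) -> tuple[InfusionCommand, DFLState]:
    """Functional wrapper: one control tick -> (command, controller state)."""
    cmd = controller.step(map_estimate, t)
    return cmd, controller.state
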