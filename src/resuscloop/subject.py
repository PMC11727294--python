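"""Synthetic hemodynamic subject: a volume-responsive hemorrhaged plant.

The live test article in the original controller studies was a swine (or a
hardware-in-the-loop testbed).  Here the plant is a lumped circulating-volume
model: MAP is a smooth, monotone, saturating function of circulating volume,
parameterized so that its local slope at the operating point equals the
subject's volume responsiveness (the dP/dV that the adaptive controller
estimates on-line).  Whole blood restores effective volume 1:1; crystalloid
(lactated Ringer's) is retained at a configurable fraction.  Lactate
accumulates while the subject is hypoperfused and clears slowly above the
ischemic threshold.

Two plant forms are provided:

``saturating`` (default)
    MAP(V) = floor + (p_max - floor) * (1 - exp(-(V - V_floor)/V_scale)),
    calibrated so MAP(V0) = baseline and dMAP/dV|_{V0} = responsiveness
    slope.  The curve steepens at low volume, so small boluses in deep
    shock restore pressure quickly — the behavior observed in vivo.

``linear``
    MAP = baseline + slope * (V - V0), clipped to [floor, 200].  An ideal
    plant for controller oracles (the pressure-volume regression is exact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .trace import ValidationError


@dataclass
class SubjectSpec:
    """Distribution parameters for drawing a synthetic subject.

    Baseline MAP spans the range seen across study animals (55-85 mmHg).
    Volume responsiveness at baseline is drawn so that closed-loop rise
    times land in the couple-of-minutes range reported for swine.
    """

    baseline_range: tuple[float, float] = (55.0, 85.0)
    slope_range: tuple[float, float] = (0.065, 0.095)  # mmHg/mL at baseline
    noise_sd: float = 1.5  # mmHg additive observation noise
    lr_retention: float = 0.3  # fraction of LR volume retained intravascularly
    blood_volume_ml: float = 2800.0  # ~40 kg swine at 70 mL/kg
    p_floor: float = 20.0  # mmHg, deep-shock pressure floor
    p_max_offset: float = 20.0  # asymptote = baseline + offset, mmHg
    plant: str = "saturating"  # "saturating" | "linear"
    lactate_rest: float = 0.8  # mmol/L
    lactate_k: float = 0.0075  # mmol/L per min per mmHg below threshold
    lactate_threshold_map: float = 45.0  # mmHg, onset of anaerobic accumulation
    lactate_clear: float = 0.02  # /min relaxation toward rest when perfused

    def validate(self) -> None:
        for name, (lo, hi) in (
            ("baseline_range", self.baseline_range),
            ("slope_range", self.slope_range),
        ):
            if hi < lo or lo <= 0:
                raise ValidationError(f"degenerate {name}: ({lo}, {hi})")
        if not (0 < self.lr_retention <= 1):
            raise ValidationError("lr_retention must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.plant not in ("saturating", "linear"):
            raise ValidationError(f"unknown plant form {self.plant!r}")


@dataclass
class SubjectState:
    """Mutable state of one simulated subject."""

    spec: SubjectSpec
    baseline_map: float
    responsiveness_slope: float  # mmHg/mL at the baseline operating point
    circulating_volume: float  # mL
    map_now: float  # observed (possibly noisy) MAP, mmHg
    lactate: float
    rng: np.random.Generator
    # plant constants (saturating form)
    p_max: float = 0.0
    v_scale: float = 1.0
    v_floor: float = 0.0
    reservoirs: dict = field(
        default_factory=lambda: {
            "wb_drawn": 0.0,
            "cpda": 0.0,
            "wb_reinfused": 0.0,  # during the hemorrhage phase (AutoBleed)
            "wb_resus_given": 0.0,  # during resuscitation (counts toward WB cap)
            "lr_given": 0.0,
        }
    )

    # -- plant -----------------------------------------------------------

    def map_clean(self, volume: Optional[float] = None) -> float:
        """Noise-free MAP at a given (default: current) circulating volume."""
        v = self.circulating_volume if volume is None else volume
        s = self.spec
        if s.plant == "linear":
            p = self.baseline_map + self.responsiveness_slope * (
                v - s.blood_volume_ml
            )
            return float(np.clip(p, s.p_floor, 200.0))
        if v <= self.v_floor:
            return s.p_floor
        return float(
            self.p_max
            - (self.p_max - s.p_floor) * math.exp(-(v - self.v_floor) / self.v_scale)
        )

    @property
    def blood_bank_ml(self) -> float:
        """Withdrawn whole blood still in the reservoir (FIFO, oldest first)."""
        r = self.reservoirs
        return r["wb_drawn"] - r["wb_reinfused"] - r["wb_resus_given"]


def make_subject(spec: Optional[SubjectSpec] = None, seed: Optional[int] = None) -> SubjectState:
    """Draw a reproducible synthetic subject from ``spec``."""
    spec = spec or SubjectSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    baseline = float(rng.uniform(*spec.baseline_range))
    slope = float(rng.uniform(*spec.slope_range))
    p_max = baseline + spec.p_max_offset
    # Calibrate the saturating curve: MAP(V0)=baseline, dMAP/dV|V0 = slope.
    v_scale = (p_max - baseline) / slope
    v_floor = spec.blood_volume_ml - v_scale * math.log(
        (p_max - spec.p_floor) / (p_max - baseline)
    )
    state = SubjectState(
        spec=spec,
        baseline_map=baseline,
        responsiveness_slope=slope,
        circulating_volume=spec.blood_volume_ml,
        map_now=baseline,
        lactate=spec.lactate_rest,
        rng=rng,
        p_max=p_max,
        v_scale=v_scale,
        v_floor=v_floor,
    )
    state.map_now = observe_map(state)
    return state


def observe_map(state: SubjectState) -> float:
    """Observed MAP: clean plant output plus seeded Gaussian noise."""
    p = state.map_clean()
    if state.spec.noise_sd > 0:
        p += float(state.rng.normal(0.0, state.spec.noise_sd))
    return max(p, 0.0)


def plant_step(
    state: SubjectState,
    infusion_rate: float = 0.0,
    fluid: str = "WB",
    hemorrhage_rate: float = 0.0,
    dt: float = 1.0,
) -> SubjectState:
    """Advance the plant by ``dt`` seconds under zero-order-hold pump rates.

    Rates are mL/min; volume changes by (effective infusion - hemorrhage)*dt.
    WB counts 1:1 toward effective volume, LR at ``lr_retention``:1.
    Mutates and returns ``state``.
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    if infusion_rate < 0 or hemorrhage_rate < 0:
        raise ValidationError("rates must be >= 0")
    retention = 1.0 if fluid == "WB" else state.spec.lr_retention
    dv = (infusion_rate * retention - hemorrhage_rate) * dt / 60.0
    state.circulating_volume = max(state.circulating_volume + dv, 1.0)
    state.map_now = observe_map(state)
    return state


def lactate_step(state: SubjectState, dt: float = 1.0) -> float:
    """Advance lactate kinetics by ``dt`` seconds.

    Accumulates linearly in hypotension depth below the ischemic MAP
    threshold; relaxes exponentially toward the resting level otherwise.
    Uses the noise-free MAP (perfusion follows true pressure).
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    s = state.spec
    p = state.map_clean()
    dt_min = dt / 60.0
    depth = s.lactate_threshold_map - p
    if depth > 0:
        state.lactate += s.lactate_k * depth * dt_min
    else:
        state.lactate += (
            -s.lactate_clear * (state.lactate - s.lactate_rest) * dt_min
        )
    state.lactate = max(state.lactate, 0.0)
    return state.lactate


def draw_blood(state: SubjectState, volume_ml: float, cpda_ratio: float = 7.0) -> None:
    """Bookkeeping for AutoBleed withdrawal: bank the blood, mix CPDA-1 1:ratio."""
    if volume_ml < 0:
        raise ValidationError("volume must be >= 0")
    state.reservoirs["wb_drawn"] += volume_ml
    state.reservoirs["cpda"] += volume_ml / cpda_ratio


def resuscitation_supply(
    state: SubjectState, requested_rate: float, wb_cap: float = 1000.0
) -> tuple[str, float]:
    """Which fluid the resuscitation pump delivers right now, and at what rate.

    Autologous whole blood is given back first (oldest first, realized as a
    FIFO volume ledger) until either the WB cap or the banked volume is
    exhausted, after which the infusate switches to lactated Ringer's.
    Pure query - no state mutation; the simulation loop does the ledger
    updates via :func:`deliver_resuscitation`.
    """
    if requested_rate < 0:
        raise ValidationError("requested_rate must be >= 0")
    if requested_rate == 0:
        return ("none", 0.0)
    wb_left = min(
        wb_cap - state.reservoirs["wb_resus_given"],
        state.blood_bank_ml,
    )
    if wb_left > 1e-9:
        return ("WB", requested_rate)
    return ("LR", requested_rate)


def deliver_resuscitation(
    state: SubjectState, requested_rate: float, wb_cap: float, dt: float
) -> str:
    """Apply one dt of resuscitation fluid, splitting exactly at the WB cap.

    Returns the fluid label delivered ("WB", "LR", "WB" if the step
    straddles the switch - the majority-WB step - or "none").
    """
    vol = requested_rate * dt / 60.0
    if vol <= 0:
        state.map_now = observe_map(state)
        return "none"
    wb_left = max(
        0.0,
        min(wb_cap - state.reservoirs["wb_resus_given"], state.blood_bank_ml),
    )
    wb_part = min(vol, wb_left)
    lr_part = vol - wb_part
    state.reservoirs["wb_resus_given"] += wb_part
    state.reservoirs["lr_given"] += lr_part
    dv = wb_part + state.spec.lr_retention * lr_part
    state.circulating_volume = max(state.circulating_volume + dv, 1.0)
    state.map_now = observe_map(state)
    return "WB" if wb_part >= lr_part else "LR"
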