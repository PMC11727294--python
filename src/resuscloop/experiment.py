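"""End-to-end protocol runner: stabilize, hemorrhage, hold, resuscitate.

The protocol mirrors the animal study timeline: a stabilization hold to
measure the baseline MAP, stepwise automated hemorrhage down to the
35-mmHg shock hold (terminated by lactate or time), then 60 minutes of
closed-loop resuscitation by the chosen controller, fed by the emulated
intermittent NIBP stream through the linear-extrapolation upsampler.  The
inner simulation step is 1 s with zero-order-hold pump rates; controllers
tick every 15 s.  Runs are deterministic given the config seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arc import AdaptiveController, ARCParams
from .autobleed import AutoBleed, autobleed_step
from .config import ExperimentConfig, resolve_target
from .dfl import FuzzyController, FuzzyPartition, RuleBase
from .io import RunRecord
from .metrics import MetricReport, controller_report
from .signal_stream import LinearUpsampler
from .subject import (
    deliver_resuscitation,
    lactate_step,
    make_subject,
    plant_step,
    resuscitation_supply,
)
from .trace import InfusionCommand, NIBPReading, PressureTrace

DT = 1.0  # inner simulation step, seconds


def build_controller(config: ExperimentConfig, target: float):
    if config.controller_kind == "ARC":
        params = ARCParams(
            target=target,
            rate_cap=min(config.max_rate, 250.0),
            control_period=config.control_period,
            **config.arc_params,
        )
        return AdaptiveController(params)
    d = dict(config.dfl_params)
    partition = d.pop("partition", None)
    rules = d.pop("rules", None)
    if isinstance(partition, dict):
        partition = FuzzyPartition(**partition)
    if isinstance(rules, dict):
        rules = RuleBase(**rules)
    if rules is None:
        rules = RuleBase(max_rate=config.max_rate)
    return FuzzyController(target=target, partition=partition, rules=rules, **d)


def run_experiment(config: ExperimentConfig) -> tuple[RunRecord, MetricReport]:
    """Run the full simulated protocol; returns the record and its metrics."""
    config.validate()
    subject = make_subject(config.subject, seed=config.seed)

    times, maps, rows = [], [], []
    commands: list[InfusionCommand] = []
    phase_marks: dict[str, float] = {}
    t = 0.0
    died = False
    low_run = 0.0  # consecutive seconds at/below the death floor

    def record(phase: str, rate: float = 0.0, fluid: str = "none") -> None:
        times.append(t)
        maps.append(subject.map_now)
        rows.append(
            {
                "time_s": t,
                "map_mmHg": subject.map_now,
                "volume_ml": subject.circulating_volume,
                "lactate_mmol_l": subject.lactate,
                "phase": phase,
                "rate_ml_min": rate,
                "fluid": fluid,
            }
        )

    def check_death() -> bool:
        nonlocal low_run, died
        if subject.map_clean() <= config.death_map:
            low_run += DT
        else:
            low_run = 0.0
        if low_run >= config.death_min * 60.0:
            died = True
        return died

    # --- stabilization -----------------------------------------------------
    stab_s = config.stabilization_min * 60.0
    while t < stab_s:
        plant_step(subject, dt=DT)
        lactate_step(subject, DT)
        record("stabilization")
        t += DT
    tail = min(60, len(maps))
    baseline = float(np.mean(maps[-tail:]))
    target = (
        config.target_map
        if config.target_map is not None
        else resolve_target(baseline)
    )

    # --- stepwise hemorrhage (AutoBleed) ------------------------------------
    phase_marks["hemorrhage_start"] = t
    bleeder = AutoBleed(config.protocol, baseline)
    p = config.protocol
    budget_s = t + len(bleeder.steps) * (p.hold_min * 60 + 1200) + (
        p.bottom_hold_max_min * 60 + 1200
    )
    while not bleeder.done and t < budget_s:
        rate, _ = autobleed_step(bleeder, subject, t, DT)
        plant_step(
            subject,
            infusion_rate=max(-rate, 0.0),
            fluid="WB",
            hemorrhage_rate=max(rate, 0.0),
            dt=DT,
        )
        lactate_step(subject, DT)
        phase = "bottom_hold" if (bleeder.at_bottom and bleeder.phase == "hold") else "hemorrhage"
        if phase == "bottom_hold" and "bottom_hold_start" not in phase_marks:
            phase_marks["bottom_hold_start"] = t
        record(phase, rate=-rate if rate < 0 else rate)
        t += DT
        if check_death():
            break

    # --- controller resuscitation -------------------------------------------
    resus_start = t
    if not died:
        phase_marks["resus_start"] = t
    controller = build_controller(config, target)
    upsampler = LinearUpsampler()
    last_reading: NIBPReading | None = None
    resus_s = config.resus_duration_min * 60.0
    rate = 0.0
    fluid_cmd = "none"
    while not died and t - resus_start < resus_s:
        t_rel = t - resus_start
        if t_rel % config.nibp_period < DT / 2:
            last_reading = NIBPReading(time=t_rel, value=max(subject.map_now, 0.0))
            upsampler.add_reading(last_reading)
        if t_rel % config.control_period < DT / 2:
            if config.input_source == "continuous":
                est = subject.map_now
            elif config.input_source == "intermittent":
                est = last_reading.value if last_reading else subject.map_now
            else:
                est = upsampler.estimate(t_rel)
            cmd = controller.step(est, t_rel)
            rate = float(np.clip(cmd.rate_ml_min, 0.0, config.max_rate))
            fluid_cmd = resuscitation_supply(subject, rate, config.wb_cap)[0]
            commands.append(
                InfusionCommand(time=t, rate_ml_min=rate, fluid=fluid_cmd)
            )
        fluid = deliver_resuscitation(subject, rate, config.wb_cap, DT)
        lactate_step(subject, DT)
        record("resuscitation", rate=rate, fluid=fluid)
        t += DT
        if check_death():
            break
    if "resus_start" in phase_marks and t > resus_start:
        phase_marks["resus_end"] = t

    trace = PressureTrace(np.array(times), np.array(maps))
    metrics = None
    if commands and "resus_end" in phase_marks:
        resus_trace = trace.window(
            resus_start, phase_marks["resus_end"], rezero=True
        )
        resus_cmds = [
            InfusionCommand(c.time - resus_start, c.rate_ml_min, c.fluid)
            for c in commands
        ]
        metrics = controller_report(resus_trace, resus_cmds, target)
    log = pd.DataFrame(rows)
    record_out = RunRecord(
        pressure_trace=trace,
        commands=commands,
        phase_marks=phase_marks,
        subject_log=log,
        metrics=metrics,
        target_map=target,
        baseline_map=baseline,
        died=died,
        meta={
            "seed": config.seed,
            "controller": config.controller_kind,
            "input_source": config.input_source,
            "true_baseline": subject.baseline_map,
            "true_slope": subject.responsiveness_slope,
            "reservoirs": dict(subject.reservoirs),
        },
    )
    record_out.validate()
    return record_out, metrics
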