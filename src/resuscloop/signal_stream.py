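"""Intermittent NIBP emulation and linear-extrapolation upsampling.

Resuscitation controllers in this package were designed around a 15-s MAP
input cadence, but a non-invasive cuff delivers one reading per minute.
This module (a) emulates the intermittent cuff feed by sampling a continuous
arterial trace once per period, and (b) restores the 15-s cadence by linear
extrapolation through the two most recent valid readings, re-anchored every
time a fresh reading arrives.  Until two readings exist the upsampler simply
passes the raw reading through.
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from .trace import NIBPReading, PressureTrace, ValidationError


class LogisticDropout:
    """Pressure-dependent cuff-failure model.

    Failure probability rises as MAP falls (cuff readings fail more often at
    low pressures):  p_fail(map) = 1 / (1 + exp((map - midpoint) / scale)).
    Only used to exercise the reliability metric; off by default.
    """

    def __init__(self, midpoint: float = 40.0, scale: float = 2.0):
        if scale <= 0:
            raise ValidationError("scale must be > 0")
        self.midpoint = float(midpoint)
        self.scale = float(scale)

    def p_fail(self, map_mmHg: float) -> float:
        z = np.clip((map_mmHg - self.midpoint) / self.scale, -500, 500)
        return float(1.0 / (1.0 + math.exp(z)))


def emulate_nibp(
    trace: PressureTrace,
    period: float = 60.0,
    dropout_model: Optional[LogisticDropout] = None,
    seed: Optional[int] = None,
) -> list[NIBPReading]:
    """Sample a continuous trace once per ``period`` seconds.

    The reading equals the instantaneous trace value at the sample instant
    (no cuff inflation delay is modeled).  An optional dropout model marks
    readings invalid; invalid readings carry value 0 (a failed cuff read).
    """
    if period <= 0:
        raise ValidationError("period must be > 0")
    if len(trace) > 1 and period < trace.dt:
        raise ValidationError("period shorter than trace resolution")
    rng = np.random.default_rng(seed)
    t0, t1 = trace.times[0], trace.times[-1]
    sample_times = np.arange(t0, t1 + 1e-9, period)
    readings = []
    for t in sample_times:
        v = float(trace.at(t))
        valid = True
        if dropout_model is not None and rng.random() < dropout_model.p_fail(v):
            valid, v = False, 0.0
        readings.append(NIBPReading(time=float(t), value=v, valid=valid))
    return readings


def upsample_extrapolate(
    r_prev: NIBPReading,
    r_last: NIBPReading,
    nibp_period: float = 60.0,
    control_period: float = 15.0,
    clamp: Optional[tuple[float, float]] = None,
) -> list[tuple[float, float]]:
    """Project MAP estimates over the next NIBP interval.

    Fits the line through the two most recent valid readings and evaluates
    it at the ``nibp_period / control_period`` future control instants
    (e.g. +15/+30/+45/+60 s after the latest reading).  Stateless: the
    caller re-invokes on every new reading, which corrects the estimate.
    """
    if not (r_prev.valid and r_last.valid):
        raise ValidationError("both readings must be valid")
    if r_last.time == r_prev.time:
        raise ValidationError("readings must have distinct times")
    n = int(round(nibp_period / control_period))
    if n < 1 or abs(n * control_period - nibp_period) > 1e-9:
        raise ValidationError("control_period must divide nibp_period")
    slope = (r_last.value - r_prev.value) / (r_last.time - r_prev.time)
    out = []
    for k in range(1, n + 1):
        t = r_last.time + k * control_period
        v = r_last.value + slope * (t - r_last.time)
        if clamp is not None:
            v = float(np.clip(v, *clamp))
        out.append((t, v))
    return out


class LinearUpsampler:
    """Stateful wrapper used by the online control loop.

    Holds the two most recent *valid* readings; :meth:`estimate` evaluates
    the line through them at an arbitrary instant.  With fewer than two
    valid readings it passes the last raw valid reading through (startup
    behavior); invalid readings are ignored rather than extrapolated from.
    """

    def __init__(self, clamp: Optional[tuple[float, float]] = None):
        self._pair: list[NIBPReading] = []
        self.clamp = clamp

    def add_reading(self, reading: NIBPReading) -> None:
        if reading.valid:
            self._pair.append(reading)
            if len(self._pair) > 2:
                self._pair.pop(0)

    @property
    def n_valid(self) -> int:
        return len(self._pair)

    def estimate(self, t: float) -> Optional[float]:
        if not self._pair:
            return None
        if len(self._pair) == 1:
            v = self._pair[0].value
        else:
            a, b = self._pair
            slope = (b.value - a.value) / (b.time - a.time)
            v = b.value + slope * (t - b.time)
        if self.clamp is not None:
            v = float(np.clip(v, *self.clamp))
        return float(v)


def stream_to_controller(
    readings: Sequence[NIBPReading] | Iterable[NIBPReading],
    control_period: float = 15.0,
    nibp_period: float = 60.0,
    end_time: Optional[float] = None,
    clamp: Optional[tuple[float, float]] = None,
) -> Iterator[tuple[float, float]]:
    """Yield one (time, MAP estimate) pair per control tick.

    Ticks start at the first reading time and step by ``control_period`` up
    to ``end_time`` (default: last reading time + one NIBP interval, i.e.
    the horizon the final projection covers, exclusive).  Each tick uses all
    readings with time <= tick time, so estimates refresh as readings arrive.
    """
    readings = list(readings)
    if not readings:
        return
    if abs(round(nibp_period / control_period) * control_period - nibp_period) > 1e-9:
        raise ValidationError("control_period must divide nibp_period")
    if end_time is None:
        end_time = readings[-1].time + nibp_period
    ups = LinearUpsampler(clamp=clamp)
    idx = 0
    t = readings[0].time
    while t < end_time - 1e-9:
        while idx < len(readings) and readings[idx].time <= t + 1e-9:
            ups.add_reading(readings[idx])
            idx += 1
        est = ups.estimate(t)
        if est is not None:
            yield (float(t), est)
        t += control_period
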