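"""Core time-series containers: pressure traces and NIBP readings.

A :class:`PressureTrace` is the package's common currency — a sampled mean
arterial pressure (MAP) series on a seconds time base.  Traces may be the
continuous plant output, the intermittent cuff-style feed, or one of the
reconstructed/upsampled variants, distinguished by ``label``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TRACE_LABELS = (
    "continuous",
    "streamed",
    "intermittent",
    "upsampled",
    "cuff",
    "ppg_pred",
)


class ValidationError(ValueError):
    """Raised when an input violates a structural precondition."""


@dataclass
class PressureTrace:
    """A sampled MAP series.

    Parameters
    ----------
    times : array-like
        Sample instants in seconds, strictly increasing.
    values : array-like
        MAP in mmHg, finite.
    label : str
        One of :data:`TRACE_LABELS`.
    meta : dict
        Free-form provenance (e.g. rows dropped while parsing).
    """

    times: np.ndarray
    values: np.ndarray
    label: str = "continuous"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValidationError("times and values must be 1-D")
        if self.times.size != self.values.size:
            raise ValidationError("times and values must have equal length")
        if self.times.size == 0:
            raise ValidationError("empty trace")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("pressure values must be finite")
        if self.label not in TRACE_LABELS:
            raise ValidationError(f"unknown trace label {self.label!r}")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> float:
        """Duration covered by the trace, seconds."""
        return float(self.times[-1] - self.times[0])

    @property
    def dt(self) -> float:
        """Median sampling period, seconds."""
        return float(np.median(np.diff(self.times))) if len(self) > 1 else np.nan

    def at(self, t) -> np.ndarray:
        """Linearly interpolated value at time(s) ``t`` (clamped at the ends)."""
        return np.interp(t, self.times, self.values)

    def window(self, t0: float, t1: float, rezero: bool = False) -> "PressureTrace":
        """Sub-trace with ``t0 <= t <= t1``; optionally restart the clock at 0."""
        m = (self.times >= t0) & (self.times <= t1)
        if not np.any(m):
            raise ValidationError("window contains no samples")
        times = self.times[m] - (t0 if rezero else 0.0)
        return PressureTrace(times, self.values[m], label=self.label)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.times, "map_mmHg": self.values})


@dataclass
class NIBPReading:
    """One intermittent (cuff-style) blood-pressure measurement.

    ``valid=False`` marks a failed reading (cuffs commonly fail to read at
    low pressure); its value is then treated as missing downstream.
    """

    time: float
    value: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and (not np.isfinite(self.value) or self.value < 0):
            raise ValidationError("valid reading must have a finite value >= 0")


@dataclass
class InfusionCommand:
    """A commanded pump rate, held (zero-order) until the next command."""

    time: float
    rate_ml_min: float
    fluid: str = "WB"  # "WB" | "LR" | "none"
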