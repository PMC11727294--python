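"""CSV/JSON readers and writers for traces, command logs and run records.

CSV dialect: comma-separated, header row, '.' decimal.  Metrics go to JSON.
Trace round-trips (write then read) are value-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .metrics import MetricReport
from .trace import InfusionCommand, PressureTrace, ValidationError

DEFAULT_COLUMNS = {"time": "time_s", "value": "map_mmHg"}


@dataclass
class RunRecord:
    """Everything one simulated protocol run produced."""

    pressure_trace: PressureTrace
    commands: list  # of InfusionCommand
    phase_marks: dict  # name -> time s, strictly increasing in protocol order
    subject_log: Optional[pd.DataFrame] = None
    metrics: Optional[MetricReport] = None
    target_map: float = float("nan")
    baseline_map: float = float("nan")
    died: bool = False
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        marks = list(self.phase_marks.values())
        if any(b <= a for a, b in zip(marks, marks[1:])):
            raise ValidationError("phase_marks must be strictly increasing")
        t0, t1 = self.pressure_trace.times[0], self.pressure_trace.times[-1]
        for c in self.commands:
            if not (t0 <= c.time <= t1):
                raise ValidationError("command time outside the trace span")


def read_trace(path, column_map: Optional[dict] = None) -> PressureTrace:
    """Read a CSV pressure trace (seconds, mmHg).

    Rows with NaN pressure are dropped with a warning (the count is kept in
    ``trace.meta['dropped_rows']``); duplicate timestamps keep the first
    occurrence.  Non-monotone time is rejected.
    """
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as e:
        raise ValidationError(f"malformed trace CSV {path}: {e}") from e
    for c in (cols["time"], cols["value"]):
        if c not in df.columns:
            raise ValidationError(f"trace CSV missing column {c!r}")
    t = df[cols["time"]].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValidationError("time column must be monotone non-decreasing")
    v = df[cols["value"]].to_numpy(dtype=float)
    keep = np.isfinite(v)
    dropped = int(np.sum(~keep))
    if dropped:
        warnings.warn(f"dropped {dropped} NaN pressure row(s)", stacklevel=2)
    t, v = t[keep], v[keep]
    # collapse exact duplicate timestamps (keep first)
    uniq = np.concatenate(([True], np.diff(t) > 0))
    trace = PressureTrace(t[uniq], v[uniq], meta={"dropped_rows": dropped})
    return trace


def write_trace(trace: PressureTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)


def commands_to_frame(commands: list) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": [c.time for c in commands],
            "rate_ml_min": [c.rate_ml_min for c in commands],
            "fluid": [c.fluid for c in commands],
        }
    )


def read_commands(path) -> list:
    df = pd.read_csv(path)
    return [
        InfusionCommand(time=r.time_s, rate_ml_min=r.rate_ml_min, fluid=r.fluid)
        for r in df.itertuples()
    ]


def write_run(record: RunRecord, out_dir) -> list[str]:
    """Write a run to ``out_dir``; returns the manifest of files written.

    Always writes trace.csv, commands.csv and metrics.json; subject_log.csv
    is added when a subject log is present.
    """
    record.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []

    write_trace(record.pressure_trace, out / "trace.csv")
    manifest.append("trace.csv")

    commands_to_frame(record.commands).to_csv(out / "commands.csv", index=False)
    manifest.append("commands.csv")

    payload = {
        "target_map": record.target_map,
        "baseline_map": record.baseline_map,
        "died": record.died,
        "phase_marks": record.phase_marks,
        "metrics": record.metrics.to_dict() if record.metrics else None,
    }
    (out / "metrics.json").write_text(json.dumps(payload, indent=2))
    manifest.append("metrics.json")

    if record.subject_log is not None:
        record.subject_log.to_csv(out / "subject_log.csv", index=False)
        manifest.append("subject_log.csv")
    return manifest
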