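"""PPG preprocessing, feature derivation, segmentation and synthesis.

The photoplethysmogram (PPG) is an optical pulse waveform whose morphology
co-varies with blood pressure.  The pipeline here mirrors standard
PPG-to-MAP practice: band-pass filter (2nd-order Butterworth, 0.5-10 Hz,
zero-phase), replace gross outliers (beyond 1.5x the IQR) by linear
interpolation, stack the signal with its 1st-4th derivatives, and cut the
result into 20-s segments of 2000 samples at 100 Hz, each labeled with the
mean MAP over the window.

A synthetic generator produces a pulse waveform whose heart rate, pulse
amplitude and dicrotic-notch position are deterministic monotone functions
of the instantaneous MAP (plus seeded noise), so a learnable MAP signal is
present in the waveform by construction.  Generative model, per beat of
period T = 60/HR(MAP):

    HR  = clip(180 - 1.1 * MAP, 60, 200)          beats/min
    A   = 0.25 + 0.011 * MAP                      systolic amplitude, a.u.
    pos = clip(0.45 + 0.002 * MAP, 0.45, 0.75)    notch position, fraction of T

    pulse(t) = A * g(t; 0.28T, 0.09T) + 0.38A * g(t; pos*T, 0.12T)

with g a Gaussian bump, plus additive white noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .trace import PressureTrace, ValidationError


@dataclass
class PPGRecord:
    """A PPG waveform with optional time-aligned MAP labels."""

    times: np.ndarray  # s, uniform
    samples: np.ndarray  # arbitrary units
    rate: float  # Hz
    subject_id: str = "s0"
    aligned_map: Optional[np.ndarray] = None  # mmHg, same length as samples

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValidationError("rate must be > 0")
        if self.times.shape != self.samples.shape:
            raise ValidationError("times and samples must align")
        if self.aligned_map is not None:
            self.aligned_map = np.asarray(self.aligned_map, dtype=float)
            if self.aligned_map.shape != self.samples.shape:
                raise ValidationError("aligned_map must align with samples")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0]) if self.times.size else 0.0


@dataclass
class PPGSegment:
    """One model input: 5 feature rows x 2000 samples, one MAP label."""

    features: np.ndarray  # (5, n_samples)
    label: float  # mean MAP over the window, mmHg
    subject_id: str
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[0] != 5:
            raise ValidationError("segment features must be 5 x n")
        if not np.all(np.isfinite(self.features)):
            raise ValidationError("segment features must be finite")


def interpolate_outliers(x: np.ndarray, iqr_factor: float = 1.5) -> np.ndarray:
    """Replace samples outside [Q1 - f*IQR, Q3 + f*IQR] by linear
    interpolation between their nearest in-range neighbors."""
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    bad = (x < q1 - iqr_factor * iqr) | (x > q3 + iqr_factor * iqr)
    if not np.any(bad) or np.all(bad):
        return x
    idx = np.arange(x.size)
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def preprocess_ppg(
    record: PPGRecord,
    target_rate: float = 100.0,
    band: tuple[float, float] = (0.5, 10.0),
    iqr_factor: float = 1.5,
    min_duration: float = 5.0,
) -> PPGRecord:
    """Downsample to 100 Hz, band-pass filter, interpolate IQR outliers.

    Filtering is zero-phase (forward-backward 2nd-order Butterworth) so the
    derivative features carry no phase lag.  Samples outside
    [Q1 - f*IQR, Q3 + f*IQR] of the filtered signal are replaced by linear
    interpolation between their in-range neighbors.
    """
    if record.rate < target_rate:
        raise ValidationError("record rate must be >= the working rate")
    if record.duration < min_duration:
        raise ValidationError(
            f"record shorter than filter warm-up ({min_duration} s)"
        )
    x = record.samples
    fs = record.rate
    if fs > target_rate:
        down = fs / target_rate
        if abs(down - round(down)) > 1e-9:
            raise ValidationError("rate must be an integer multiple of 100 Hz")
        x = sps.resample_poly(x, up=1, down=int(round(down)))
        fs = target_rate
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    x = interpolate_outliers(x, iqr_factor)
    times = record.times[0] + np.arange(x.size) / fs
    aligned = None
    if record.aligned_map is not None:
        aligned = np.interp(times, record.times, record.aligned_map)
    return PPGRecord(
        times=times,
        samples=x,
        rate=fs,
        subject_id=record.subject_id,
        aligned_map=aligned,
    )


def derive_features(record: PPGRecord) -> np.ndarray:
    """Stack the signal with its successive 1st-4th time derivatives.

    Each order is a central difference applied to the previous order
    (one-sided at the edges), scaled to per-second units.  Returns a
    (5, n) array.
    """
    rows = [record.samples]
    d = record.samples
    dt = 1.0 / record.rate
    for _ in range(4):
        d = np.gradient(d, dt)
        rows.append(d)
    return np.vstack(rows)


def segment_ppg(
    features: np.ndarray,
    aligned_map: np.ndarray,
    rate: float = 100.0,
    window_s: float = 20.0,
    overlap_s: float = 0.0,
    subject_id: str = "s0",
) -> list[PPGSegment]:
    """Cut a (5, n) feature stack into labeled fixed-length windows.

    Windows are 20 s (2000 samples at 100 Hz) and non-overlapping by
    default; the trailing partial window is dropped.  The label is the mean
    aligned MAP over the window.
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[1]
    win = int(round(window_s * rate))
    step = int(round((window_s - overlap_s) * rate))
    if step <= 0:
        raise ValidationError("overlap must be shorter than the window")
    segments = []
    for start in range(0, n - win + 1, step):
        sl = slice(start, start + win)
        segments.append(
            PPGSegment(
                features=features[:, sl],
                label=float(np.mean(aligned_map[sl])),
                subject_id=subject_id,
                start_time=start / rate,
            )
        )
    return segments


@dataclass
class MorphologyParams:
    """MAP -> waveform coupling of the synthetic PPG generator."""

    hr_intercept: float = 180.0  # bpm at MAP 0 (before clipping)
    hr_slope: float = -1.1  # bpm per mmHg
    hr_bounds: tuple[float, float] = (60.0, 200.0)
    amp_intercept: float = 0.25  # a.u.
    amp_slope: float = 0.011  # a.u. per mmHg
    notch_intercept: float = 0.45  # fraction of beat period
    notch_slope: float = 0.002  # per mmHg
    notch_bounds: tuple[float, float] = (0.45, 0.75)
    notch_amp_frac: float = 0.38
    systolic_pos: float = 0.28  # fraction of beat period
    systolic_width: float = 0.09
    notch_width: float = 0.12
    noise_sd: float = 0.05  # a.u.

    def heart_rate(self, map_mmHg: float) -> float:
        return float(
            np.clip(self.hr_intercept + self.hr_slope * map_mmHg, *self.hr_bounds)
        )

    def amplitude(self, map_mmHg: float) -> float:
        return self.amp_intercept + self.amp_slope * map_mmHg

    def notch_pos(self, map_mmHg: float) -> float:
        return float(
            np.clip(
                self.notch_intercept + self.notch_slope * map_mmHg,
                *self.notch_bounds,
            )
        )


def synth_ppg(
    map_trace: PressureTrace,
    morphology: Optional[MorphologyParams] = None,
    seed: Optional[int] = None,
    rate: float = 100.0,
    subject_id: str = "s0",
) -> PPGRecord:
    """Generate a pulse-morphology PPG whose features track the MAP trace."""
    m = morphology or MorphologyParams()
    rng = np.random.default_rng(seed)
    t0, t1 = map_trace.times[0], map_trace.times[-1]
    n = int(round((t1 - t0) * rate)) + 1
    times = t0 + np.arange(n) / rate
    x = np.zeros(n)
    beat_start = t0
    while beat_start < t1:
        local_map = float(map_trace.at(beat_start))
        period = 60.0 / m.heart_rate(local_map)
        amp = m.amplitude(local_map)
        centers = (
            beat_start + m.systolic_pos * period,
            beat_start + m.notch_pos(local_map) * period,
        )
        widths = (m.systolic_width * period, m.notch_width * period)
        amps = (amp, m.notch_amp_frac * amp)
        i0 = max(0, int((beat_start - t0 - 0.5 * period) * rate))
        i1 = min(n, int((beat_start - t0 + 1.5 * period) * rate))
        tt = times[i0:i1]
        for c, w, a in zip(centers, widths, amps):
            x[i0:i1] += a * np.exp(-0.5 * ((tt - c) / w) ** 2)
        beat_start += period
    if m.noise_sd > 0:
        x += rng.normal(0.0, m.noise_sd, size=n)
    aligned = map_trace.at(times)
    return PPGRecord(
        times=times, samples=x, rate=rate, subject_id=subject_id, aligned_map=aligned
    )


def make_map_profile(
    baseline: float,
    duration_s: float = 240.0,
    nadir: float = 35.0,
    recovery: float = 65.0,
    dt: float = 0.5,
    seed: Optional[int] = None,
) -> PressureTrace:
    """A hemorrhage-and-resuscitation-shaped MAP profile for PPG synthesis.

    Baseline hold, descent to the shock nadir, hypovolemic hold, rapid
    recovery toward the resuscitation target, final hold — plus slow
    seeded wander.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + dt / 2, dt)
    f = t / duration_s
    knots_f = np.array([0.0, 0.20, 0.50, 0.70, 0.80, 1.0])
    knots_v = np.array(
        [baseline, baseline, nadir, nadir, min(recovery, baseline), min(recovery, baseline)]
    )
    v = np.interp(f, knots_f, knots_v)
    wander = rng.normal(0.0, 1.0, size=t.size)
    kernel = np.hanning(41)
    wander = np.convolve(wander, kernel / kernel.sum(), mode="same") * 3.0
    return PressureTrace(t, v + wander, label="continuous")


def make_ppg_dataset(
    n_subjects: int = 6,
    duration_s: float = 240.0,
    seed: int = 0,
    rate: float = 100.0,
    morphology: Optional[MorphologyParams] = None,
) -> list[PPGRecord]:
    """Seeded bank of synthetic subjects with MAP-coupled PPG waveforms."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_subjects):
        baseline = float(rng.uniform(60.0, 80.0))
        profile = make_map_profile(
            baseline, duration_s=duration_s, seed=int(rng.integers(2**31))
        )
        rec = synth_ppg(
            profile,
            morphology=morphology,
            seed=int(rng.integers(2**31)),
            rate=rate,
            subject_id=f"s{i}",
        )
        records.append(rec)
    return records


def records_to_segments(
    records: list[PPGRecord], window_s: float = 20.0, overlap_s: float = 0.0
) -> list[PPGSegment]:
    """Full preprocessing path: filter -> derivatives -> labeled segments."""
    segments = []
    for rec in records:
        clean = preprocess_ppg(rec)
        feats = derive_features(clean)
        segments.extend(
            segment_ppg(
                feats,
                clean.aligned_map,
                rate=clean.rate,
                window_s=window_s,
                overlap_s=overlap_s,
                subject_id=clean.subject_id,
            )
        )
    return segments
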