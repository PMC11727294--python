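import numpy as np
import pytest

from resuscloop import PressureTrace, SubjectSpec, make_subject


@pytest.fixture
def constant_trace():
    def _make(value=65.0, duration=300.0, dt=1.0, label="continuous"):
        t = np.arange(0.0, duration + dt / 2, dt)
        return PressureTrace(t, np.full(t.size, value), label=label)

    return _make


@pytest.fixture
def affine_trace():
    def _make(intercept=60.0, slope_per_s=0.1, duration=300.0, dt=1.0):
        t = np.arange(0.0, duration + dt / 2, dt)
        return PressureTrace(t, intercept + slope_per_s * t)

    return _make


@pytest.fixture
def noiseless_subject():
    def _make(baseline=65.0, slope=0.08, plant="saturating", seed=0):
        spec = SubjectSpec(
            baseline_range=(baseline, baseline),
            slope_range=(slope, slope),
            noise_sd=0.0,
            plant=plant,
        )
        return make_subject(spec, seed=seed)

    return _make
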