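import numpy as np
import pytest

from scvoice.audio import FEATURE_NAMES, VoiceRecording
from scvoice.synthetic import CohortSpec, generate_cohort


def sine_recording(freq=220.0, duration=1.0, amplitude=0.3, rate=44100.0):
    t = np.arange(int(duration * rate)) / rate
    return VoiceRecording(amplitude * np.sin(2 * np.pi * freq * t), rate)


def sawtooth_recording(freq=150.0, duration=2.0, amplitude=0.3, rate=44100.0):
    t = np.arange(int(duration * rate)) / rate
    return VoiceRecording(amplitude * (2.0 * ((freq * t) % 1.0) - 1.0), rate)


@pytest.fixture(scope="session")
def small_cohort():
    """Weak-signal synthetic cohort, study-like defaults."""
    df, truth = generate_cohort(CohortSpec(n=400, sex="male", seed=11))
    return df, truth


@pytest.fixture(scope="session")
def strong_cohort():
    """Cohort with 2-SD class shifts on five features: separable classes."""
    shifts = {
        "TE": {f: 2.0 for f in ("sF0", "sI0", "sMFCC1", "sMFCC3", "sLPR1")},
        "SE": {f: -2.0 for f in ("sF0", "sSPD", "sMFCC2", "sMFCC5", "sLPR2")},
        "SY": {f: 2.0 for f in ("sSPD", "sFSTD", "sMFCC4", "sMFCC6", "sLPR3")},
    }
    df, truth = generate_cohort(
        CohortSpec(n=600, sex="male", seed=7, class_shifts=shifts, outlier_frac=0.0)
    )
    return df, truth


def zscore_features(df):
    """Plain per-column standardization, for tests that skip the
    age-window machinery."""
    out = df.copy()
    for f in FEATURE_NAMES:
        x = df[f].to_numpy(dtype=float)
        out[f] = (x - x.mean()) / x.std(ddof=1)
    return out
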