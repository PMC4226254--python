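"""Synthetic audio and cohort generation.

Two generators stand in for clinical voice data, which cannot be
redistributed:

* :func:`generate_sentence_audio` synthesizes a sentence-like
  utterance — a jittered harmonic source with a controllable spectral
  tilt, syllable-rate amplitude modulation, a noise floor and silent
  head/tail — as the pair of repetitions the feature extractor
  expects.  The two repetitions share every control parameter and
  differ only in the noise realization.

* :func:`generate_cohort` draws subjects-by-features tables with the
  statistical structure the preprocessing and modelling stages assume:
  class-dependent mean shifts, smooth age drift, correlated Gaussian
  within-class variation (the multicollinearity the L1 stage exists
  to handle) and a small fraction of planted gross outliers, recorded
  in a ground-truth sidecar.

Default cohort parameters mirror the study population the classifier
was built for: adults 15+, class mix roughly 43/24/33 (TE/SE/SY) for
men and 35/28/37 for women, and weak class separation on a handful of
features (voice alone is a weak constitutional signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audio import FEATURE_NAMES, VoiceRecording


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cohort generation

# plausible raw-scale feature levels; pitch statistics differ by sex
BASE_MEAN = {
    "sF0": {"male": 120.0, "female": 210.0},
    "sFSTD": {"male": 22.0, "female": 30.0},
    "sI0": -26.0,
    "sISTD": 6.5,
    "sSPD": 5.0,
    "sLPR1": 0.35,
    "sLPR2": 0.55,
    "sLPR3": 0.90,
    **{f"sMFCC{i}": v for i, v in enumerate(
        [-45.0, 8.0, -2.0, 1.5, -1.0, 0.8, -0.6, 0.5, -0.4, 0.3, -0.3, 0.2, -0.2]
    )},
}
BASE_SD = {
    "sF0": 18.0, "sFSTD": 8.0, "sI0": 4.0, "sISTD": 2.0, "sSPD": 0.7,
    "sLPR1": 0.30, "sLPR2": 0.30, "sLPR3": 0.45,
    **{f"sMFCC{i}": v for i, v in enumerate(
        [6.0, 3.0, 2.0, 1.5, 1.2, 1.0, 0.9, 0.8, 0.7, 0.6, 0.6, 0.5, 0.5]
    )},
}

# class mean shifts in SD units, echoing the traditional voice
# descriptions: TE thick/loud/grave, SE low/calm/slow, SY fast/high-pitched
DEFAULT_CLASS_SHIFTS = {
    "TE": {"sF0": -0.25, "sI0": 0.25, "sMFCC1": -0.2, "sLPR1": 0.2},
    "SE": {"sI0": -0.25, "sSPD": -0.3, "sISTD": -0.2, "sMFCC2": 0.2},
    "SY": {"sF0": 0.25, "sSPD": 0.3, "sFSTD": 0.2, "sMFCC3": -0.2},
}

# smooth age drift in SD units: (linear, quadratic) coefficients of
# u = (age - 45) / 20
DEFAULT_AGE_DRIFT = {
    "sF0": (-0.4, 0.1),
    "sSPD": (-0.5, -0.15),
    "sI0": (-0.2, 0.0),
    "sFSTD": (0.3, 0.1),
    "sMFCC1": (0.25, 0.0),
}

DEFAULT_CLASS_PROBS = {
    "male": {"TE": 0.43, "SE": 0.24, "SY": 0.33},
    "female": {"TE": 0.35, "SE": 0.28, "SY": 0.37},
}


def default_correlation(rho: float = 0.5) -> np.ndarray:
    """AR(1)-style positive-definite feature correlation with an extra
    strongly coupled band-power block (sLPR3 tracks sLPR1 + sLPR2)."""
    p = len(FEATURE_NAMES)
    idx = np.arange(p)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    lpr = [FEATURE_NAMES.index(f) for f in ("sLPR1", "sLPR2", "sLPR3")]
    for a in lpr:
        for b in lpr:
            if a != b:
                corr[a, b] = 0.65
    # symmetrize and nudge to guaranteed positive definiteness
    corr = (corr + corr.T) / 2
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class CohortSpec:
    """Parameters of a synthetic subjects-by-features table."""

    n: int = 600
    sex: str = "male"
    class_probs: dict[str, float] | None = None
    age_mean: float = 47.0
    age_sd: float = 16.0
    age_range: tuple[float, float] = (15.0, 85.0)
    class_shifts: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLASS_SHIFTS.items()}
    )
    age_drift: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_DRIFT)
    )
    correlation: np.ndarray | None = None
    outlier_frac: float = 0.01
    outlier_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_probs is None:
            self.class_probs = dict(DEFAULT_CLASS_PROBS[self.sex])
        probs = np.array([self.class_probs[c] for c in ("TE", "SE", "SY")])
        if abs(probs.sum() - 1.0) > 1e-9:
            raise SyntheticError("class probabilities must sum to 1")
        if not 0.0 <= self.outlier_frac <= 0.2:
            raise SyntheticError("outlier_frac must lie in [0, 0.2]")
        if self.correlation is None:
            self.correlation = default_correlation()
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (len(FEATURE_NAMES),) * 2:
            raise SyntheticError("correlation matrix must be 21 x 21")
        if np.min(np.linalg.eigvalsh((corr + corr.T) / 2)) <= 0:
            raise SyntheticError("correlation matrix must be positive definite")
        self.correlation = corr


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort table plus a ground-truth sidecar.

    Features are built in SD units as class shift + age drift +
    correlated standard Gaussian noise, then mapped to plausible raw
    scales per feature.  Planted outliers displace a random subset of
    rows by ``outlier_sd`` SDs along a random direction; their ids are
    recorded in the sidecar.
    """
    rng = np.random.default_rng(spec.seed)
    p = len(FEATURE_NAMES)
    classes = ("TE", "SE", "SY")
    probs = [spec.class_probs[c] for c in classes]
    labels = rng.choice(classes, size=spec.n, p=probs)
    ages = np.clip(
        np.round(rng.normal(spec.age_mean, spec.age_sd, size=spec.n)),
        spec.age_range[0],
        spec.age_range[1],
    )

    z = rng.multivariate_normal(
        np.zeros(p), spec.correlation, size=spec.n, method="cholesky"
    )
    for cls in classes:
        rows = labels == cls
        for feat, shift in spec.class_shifts.get(cls, {}).items():
            z[rows, FEATURE_NAMES.index(feat)] += shift
    u = (ages - 45.0) / 20.0
    for feat, (lin, quad) in spec.age_drift.items():
        z[:, FEATURE_NAMES.index(feat)] += lin * u + quad * u**2

    n_out = int(round(spec.outlier_frac * spec.n))
    outlier_rows = rng.choice(spec.n, size=n_out, replace=False) if n_out else np.array([], int)
    for i in outlier_rows:
        d = rng.normal(size=p)
        z[i] += spec.outlier_sd * d / np.linalg.norm(d)

    data = {}
    for j, feat in enumerate(FEATURE_NAMES):
        mean = BASE_MEAN[feat]
        if isinstance(mean, dict):
            mean = mean[spec.sex]
        data[feat] = mean + BASE_SD[feat] * z[:, j]

    prefix = spec.sex[0].upper()
    df = pd.DataFrame(
        {
            "subject_id": [f"{prefix}{i:05d}" for i in range(spec.n)],
            "age": ages,
            "sex": spec.sex,
            "sc_label": labels,
            **data,
        }
    )
    truth = {
        "seed": spec.seed,
        "sex": spec.sex,
        "outlier_ids": [df.loc[i, "subject_id"] for i in sorted(outlier_rows)],
        "class_counts": {c: int(np.sum(labels == c)) for c in classes},
    }
    return df, truth


# ---------------------------------------------------------------------------
# audio generation


@dataclass
class AudioSpec:
    """Parameters of a synthetic sentence-like utterance."""

    f0: float = 150.0
    f0_jitter: float = 0.01  # relative slow F0 wobble
    duration: float = 3.0  # voiced portion, s
    amplitude: float = 0.3  # peak envelope, full scale = 1
    spectral_tilt: float = -12.0  # dB/octave harmonic roll-off
    noise_floor_db: float = -50.0  # dBFS white-noise floor
    rate: float = 44100.0
    head_tail_silence: float = 0.3  # s of silence on each side
    syllable_rate: float = 0.0  # Hz of AM; 0 disables modulation
    seed: int = 0

    def __post_init__(self) -> None:
        if not 60.0 <= self.f0 <= 400.0:
            raise SyntheticError("f0 must lie in [60, 400] Hz")
        if self.duration <= 0.5:
            raise SyntheticError("duration must exceed 0.5 s")
        if self.rate < 8000.0:
            raise SyntheticError("rate must be at least 8000 Hz")


def _one_utterance(spec: AudioSpec, rng: np.random.Generator) -> np.ndarray:
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    # slow multiplicative F0 wobble: smoothed white noise
    wobble = rng.normal(size=n)
    kernel = np.ones(2048) / 2048.0
    wobble = np.convolve(wobble, kernel, mode="same")
    wobble /= max(np.abs(wobble).max(), 1e-12)
    f0_t = spec.f0 * (1.0 + spec.f0_jitter * wobble)
    phase = 2.0 * np.pi * np.cumsum(f0_t) / spec.rate

    n_harm = max(1, int(4000.0 // spec.f0))
    n_harm = min(n_harm, int((spec.rate / 2.0 - 1.0) // spec.f0))
    signal = np.zeros(n)
    for k in range(1, n_harm + 1):
        amp = 10.0 ** (spec.spectral_tilt * np.log2(k) / 20.0)
        signal += amp * np.sin(k * phase)
    signal /= np.abs(signal).max()

    env = np.ones(n)
    ramp = int(0.05 * spec.rate)
    env[:ramp] = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
    env[-ramp:] = env[:ramp][::-1]
    if spec.syllable_rate > 0:
        env *= 0.75 + 0.25 * np.cos(2.0 * np.pi * spec.syllable_rate * t)
    voiced = spec.amplitude * env * signal
    voiced += 10.0 ** (spec.noise_floor_db / 20.0) * rng.normal(size=n)

    pad = np.zeros(int(round(spec.head_tail_silence * spec.rate)))
    return np.concatenate([pad, voiced, pad])


def generate_sentence_audio(
    spec: AudioSpec, subject_id: str = ""
) -> tuple[VoiceRecording, VoiceRecording]:
    """Two repetitions of the synthetic sentence, differing only in the
    jitter/noise realization."""
    rng = np.random.default_rng(spec.seed)
    recs = []
    for i in (1, 2):
        samples = _one_utterance(spec, rng)
        recs.append(VoiceRecording(samples, spec.rate, subject_id, utterance_index=i))
    return recs[0], recs[1]
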