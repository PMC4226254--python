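"""Sentence-level vocal feature extraction.

Turns a pair of sentence recordings (mono PCM WAV, nominally 44.1 kHz)
into a 21-dimensional feature vector:

* ``sF0``, ``sFSTD`` — mean and SD of the frame-wise fundamental
  frequency over voiced frames (Hz),
* ``sI0``, ``sISTD`` — mean and SD of the frame-wise RMS intensity in
  dBFS over non-silent frames,
* ``sMFCC0`` … ``sMFCC12`` — frame-averaged mel-frequency cepstral
  coefficients (HTK-style filterbank convention),
* ``sSPD`` — reading speed in syllables per second,
* ``sLPR1``, ``sLPR2``, ``sLPR3`` — base-10 log ratios of summed
  spectral power between the bands 60–240, 240–960 and 960–3840 Hz.

Analysis frames are 2048 samples (46.4 ms at 44.1 kHz) with 50 %
overlap; the power-of-two length avoids FFT zero padding.  Each
feature of the final vector is the arithmetic mean of the two
per-utterance values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft, rfftfreq
from scipy.io import wavfile
from scipy.signal.windows import hamming

FEATURE_NAMES: tuple[str, ...] = (
    "sF0",
    "sFSTD",
    "sI0",
    "sISTD",
    *[f"sMFCC{i}" for i in range(13)],
    "sSPD",
    "sLPR1",
    "sLPR2",
    "sLPR3",
)

LPR_BANDS: tuple[tuple[float, float], ...] = ((60.0, 240.0), (240.0, 960.0), (960.0, 3840.0))


class AudioFeatureError(ValueError):
    """Raised when a recording cannot yield a valid feature value."""


@dataclass(frozen=True)
class VoiceRecording:
    """A mono waveform with amplitudes scaled to [-1, 1)."""

    samples: np.ndarray
    rate: float
    subject_id: str = ""
    utterance_index: int = 1

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise AudioFeatureError("samples must be a non-empty 1-D array")
        if not self.rate > 0:
            raise AudioFeatureError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class FrameSpec:
    """Short-time analysis geometry: window length and overlap."""

    window_samples: int = 2048
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        w = self.window_samples
        if w < 2 or (w & (w - 1)) != 0:
            raise ValueError(f"window_samples must be a power of two, got {w}")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")

    @property
    def hop(self) -> int:
        return int(round(self.window_samples * (1.0 - self.overlap_fraction)))

    def duration_ms(self, rate: float) -> float:
        return 1000.0 * self.window_samples / rate


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable parameters of the extraction chain.

    Pitch search is restricted to ``f0_min``–``f0_max`` Hz and a frame
    counts as voiced when the normalized autocorrelation peak exceeds
    ``voicing_threshold``.  Frames with RMS below ``silence_db`` (dBFS,
    full scale = 1.0) are treated as silent.  MFCCs use pre-emphasis,
    a Hamming window and ``n_mels`` triangular filters from 0 to the
    Nyquist frequency, followed by an orthonormal DCT-II.
    """

    f0_min: float = 60.0
    f0_max: float = 400.0
    voicing_threshold: float = 0.45
    silence_db: float = -60.0
    preemphasis: float = 0.97
    n_mels: int = 26
    n_mfcc: int = 13
    syllable_count: int = 18


@dataclass(frozen=True)
class FeatureVector:
    """The 21 named vocal features for one subject."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != (len(FEATURE_NAMES),):
            raise AudioFeatureError(
                f"feature vector must have {len(FEATURE_NAMES)} entries, got {values.shape}"
            )
        object.__setattr__(self, "values", values)

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(FEATURE_NAMES, self.values)}


def read_wav(path, subject_id: str = "", utterance_index: int = 1) -> VoiceRecording:
    """Read a RIFF WAV file into a :class:`VoiceRecording`.

    16-bit PCM is scaled by 2**15 so full scale maps to [-1, 1).  Other
    integer widths and float data are scaled to the same convention.
    Stereo input is rejected; rates other than 44.1 kHz are accepted
    with a warning.
    """
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise AudioFeatureError(f"{path}: expected mono audio, got shape {data.shape}")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    if rate != 44100:
        warnings.warn(
            f"{path}: sampling rate {rate} Hz differs from the nominal 44100 Hz",
            stacklevel=2,
        )
    return VoiceRecording(samples, float(rate), subject_id, utterance_index)


def write_wav(path, rec: VoiceRecording) -> None:
    """Write a recording as 16-bit PCM WAV."""
    clipped = np.clip(rec.samples, -1.0, 32767.0 / 32768.0)
    wavfile.write(path, int(rec.rate), np.round(clipped * 32768.0).astype(np.int16))


def frame_signal(rec: VoiceRecording, spec: FrameSpec = FrameSpec()) -> np.ndarray:
    """Slice the waveform into overlapping full frames, shape (n_frames, W)."""
    n, w, h = rec.samples.size, spec.window_samples, spec.hop
    if n < w:
        raise AudioFeatureError(
            f"signal too short: {n} samples < one window of {w} samples"
        )
    n_frames = (n - w) // h + 1
    strides = (rec.samples.strides[0] * h, rec.samples.strides[0])
    return np.lib.stride_tricks.as_strided(
        rec.samples, shape=(n_frames, w), strides=strides
    ).copy()


def _frame_rms_db(frames: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(frames**2, axis=1))
    with np.errstate(divide="ignore"):
        return 20.0 * np.log10(rms)


def _nonsilent_mask(frames: np.ndarray, config: FeatureConfig) -> np.ndarray:
    return _frame_rms_db(frames) > config.silence_db


def _frame_f0(frame: np.ndarray, rate: float, config: FeatureConfig) -> float:
    """Autocorrelation F0 of one frame; NaN when unvoiced.

    The normalized autocorrelation is searched over the lag range
    corresponding to [f0_min, f0_max]; the peak location is refined by
    parabolic interpolation so the estimate is not quantized to whole
    sample lags.
    """
    x = frame - frame.mean()
    energy = float(np.dot(x, x))
    if energy <= 0.0:
        return np.nan
    # full autocorrelation via FFT, lags 0..W-1
    n = x.size
    nfft = 2 * n
    spec = np.abs(rfft(x, n=nfft)) ** 2
    ac = np.fft.irfft(spec, n=nfft)[:n]
    ac /= ac[0]
    lag_min = max(2, int(np.floor(rate / config.f0_max)))
    lag_max = min(n - 2, int(np.ceil(rate / config.f0_min)))
    if lag_min >= lag_max:
        return np.nan
    window = ac[lag_min : lag_max + 1]
    k = int(np.argmax(window))
    peak = window[k]
    if peak < config.voicing_threshold:
        return np.nan
    lag = lag_min + k
    # parabolic refinement around the integer-lag peak
    y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
    denom = y0 - 2.0 * y1 + y2
    delta = 0.0 if denom == 0.0 else 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return rate / (lag + delta)


def pitch_summary(
    rec: VoiceRecording,
    spec: FrameSpec = FrameSpec(),
    config: FeatureConfig = FeatureConfig(),
) -> tuple[float, float]:
    """Mean and SD of frame-wise F0 over voiced, non-silent frames."""
    frames = frame_signal(rec, spec)
    mask = _nonsilent_mask(frames, config)
    f0 = np.array(
        [
            _frame_f0(frame, rec.rate, config) if ok else np.nan
            for frame, ok in zip(frames, mask)
        ]
    )
    voiced = f0[np.isfinite(f0)]
    if voiced.size == 0:
        raise AudioFeatureError("unvoiced recording: no frame passed the voicing threshold")
    sd = float(np.std(voiced, ddof=1)) if voiced.size > 1 else 0.0
    return float(np.mean(voiced)), sd


def intensity_summary(
    rec: VoiceRecording,
    spec: FrameSpec = FrameSpec(),
    config: FeatureConfig = FeatureConfig(),
) -> tuple[float, float]:
    """Mean and SD of frame RMS intensity in dBFS over non-silent frames."""
    frames = frame_signal(rec, spec)
    db = _frame_rms_db(frames)
    db = db[db > config.silence_db]
    if db.size == 0:
        raise AudioFeatureError("silent recording: no frame above the silence threshold")
    sd = float(np.std(db, ddof=1)) if db.size > 1 else 0.0
    return float(np.mean(db)), sd


def _mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_inv(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, nfft: int, rate: float) -> np.ndarray:
    """Triangular mel filterbank, n_mels x (nfft//2 + 1), spanning 0..rate/2."""
    edges = _mel_inv(np.linspace(0.0, float(_mel(rate / 2.0)), n_mels + 2))
    freqs = rfftfreq(nfft, d=1.0 / rate)
    fb = np.zeros((n_mels, freqs.size))
    for m in range(n_mels):
        lo, mid, hi = edges[m], edges[m + 1], edges[m + 2]
        up = (freqs - lo) / (mid - lo)
        down = (hi - freqs) / (hi - mid)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb


def mfcc_summary(
    rec: VoiceRecording,
    spec: FrameSpec = FrameSpec(),
    config: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """Frame-averaged MFCC vector (coefficients 0..n_mfcc-1).

    Pre-emphasis is applied to the whole signal, frames are Hamming
    windowed, and log mel filterbank energies (floored to avoid
    log-of-zero) are mapped through an orthonormal DCT-II.  Averaging
    runs over non-silent frames so head/tail silence does not dilute
    the spectral envelope summary.
    """
    emphasized = np.append(
        rec.samples[0], rec.samples[1:] - config.preemphasis * rec.samples[:-1]
    )
    frames = frame_signal(VoiceRecording(emphasized, rec.rate), spec)
    raw_frames = frame_signal(rec, spec)
    mask = _nonsilent_mask(raw_frames, config)
    if not mask.any():
        raise AudioFeatureError("silent recording: no frame above the silence threshold")
    frames = frames[mask]
    w = spec.window_samples
    windowed = frames * hamming(w, sym=False)
    power = np.abs(rfft(windowed, axis=1)) ** 2
    fb = mel_filterbank(config.n_mels, w, rec.rate)
    energies = power @ fb.T
    log_e = np.log(np.maximum(energies, 1e-30))
    ceps = dct(log_e, type=2, norm="ortho", axis=1)[:, : config.n_mfcc]
    return ceps.mean(axis=0)


def log_power_ratios(
    rec: VoiceRecording,
    spec: FrameSpec = FrameSpec(),
    config: FeatureConfig = FeatureConfig(),
) -> tuple[float, float, float]:
    """Base-10 log power ratios between the three fixed bands.

    Band powers are summed per frame over the periodogram bins in
    [lo, hi) and averaged across frames before the ratios are taken,
    so ``sLPR3 == sLPR1 + sLPR2`` holds identically.
    """
    top = LPR_BANDS[-1][1]
    if rec.rate < 2.0 * top:
        raise AudioFeatureError(
            f"sampling rate {rec.rate} Hz below {2 * top:.0f} Hz required for the "
            f"{LPR_BANDS[-1][0]:.0f}-{top:.0f} Hz band"
        )
    frames = frame_signal(rec, spec)
    w = spec.window_samples
    windowed = frames * hamming(w, sym=False)
    power = np.abs(rfft(windowed, axis=1)) ** 2
    freqs = rfftfreq(w, d=1.0 / rec.rate)
    band_power = []
    for lo, hi in LPR_BANDS:
        mask = (freqs >= lo) & (freqs < hi)
        band_power.append(float(power[:, mask].sum(axis=1).mean()))
    p1, p2, p3 = band_power
    if min(band_power) <= 0.0:
        raise AudioFeatureError("zero spectral power in a ratio band")
    lpr1 = np.log10(p1) - np.log10(p2)
    lpr2 = np.log10(p2) - np.log10(p3)
    lpr3 = np.log10(p1) - np.log10(p3)
    return float(lpr1), float(lpr2), float(lpr3)


def speech_rate(
    rec: VoiceRecording,
    syllable_count: int,
    spec: FrameSpec = FrameSpec(),
    config: FeatureConfig = FeatureConfig(),
) -> float:
    """Syllables per second over the detected speech span.

    The speech span runs from the start of the first non-silent frame
    to the end of the last one, so padding the waveform with silence
    leaves the value unchanged.
    """
    if syllable_count <= 0:
        raise AudioFeatureError("syllable_count must be positive")
    frames = frame_signal(rec, spec)
    mask = _nonsilent_mask(frames, config)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise AudioFeatureError("silent recording: no frame above the silence threshold")
    start = idx[0] * spec.hop
    end = idx[-1] * spec.hop + spec.window_samples
    duration = (end - start) / rec.rate
    return syllable_count / duration


def extract_single(
    rec: VoiceRecording,
    spec: FrameSpec = FrameSpec(),
    config: FeatureConfig = FeatureConfig(),
) -> np.ndarray:
    """Compute the 21 features for one utterance, in FEATURE_NAMES order."""
    f0, fstd = pitch_summary(rec, spec, config)
    i0, istd = intensity_summary(rec, spec, config)
    mfcc = mfcc_summary(rec, spec, config)
    spd = speech_rate(rec, config.syllable_count, spec, config)
    lpr1, lpr2, lpr3 = log_power_ratios(rec, spec, config)
    return np.concatenate([[f0, fstd, i0, istd], mfcc, [spd, lpr1, lpr2, lpr3]])


def extract_feature_vector(
    rec1: VoiceRecording,
    rec2: VoiceRecording,
    spec: FrameSpec = FrameSpec(),
    config: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    """Average the per-utterance features of the two sentence repetitions."""
    per_utt = []
    for i, rec in enumerate((rec1, rec2), start=1):
        try:
            per_utt.append(extract_single(rec, spec, config))
        except AudioFeatureError as exc:
            raise AudioFeatureError(f"utterance {i}: {exc}") from exc
    return FeatureVector(
        (per_utt[0] + per_utt[1]) / 2.0, subject_id=rec1.subject_id or rec2.subject_id
    )
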