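"""Signal chain: Butterworth bandpass, decimation, Welch PSD, robust scaling.

The canonical trial (32 channels x 60000 samples at 30 kHz) maps to
32 x 2000 at 1 kHz after filtering and 30:1 downsampling, and to a
32 x 129 spectral feature matrix after Welch estimation (256-point Hann
window, 50% overlap, one-sided density).  Features are normalized per
(channel, bin) by subtracting the median and dividing by the
inter-quartile range, with scaler statistics fit on training trials only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .dataio import TrialRecording

__all__ = [
    "FilterSpec",
    "SpectralFeatures",
    "ScalerParams",
    "bandpass",
    "downsample",
    "welch_psd",
    "fit_scaler",
    "apply_scaler",
    "featurize_trial",
    "DOWNSAMPLE_FACTOR",
    "NPERSEG",
    "N_BINS",
]

DOWNSAMPLE_FACTOR = 30
NPERSEG = 256
NOVERLAP = 128
N_BINS = NPERSEG // 2 + 1


@dataclass(frozen=True)
class FilterSpec:
    """Fifth-order Butterworth bandpass, 0.5-100 Hz, applied forward-backward
    (zero phase), so the effective magnitude response is squared."""

    order: int = 5
    low_cut: float = 0.5
    high_cut: float = 100.0

    def __post_init__(self):
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")


@dataclass
class SpectralFeatures:
    """Per-trial channel x frequency-bin PSD matrix (power per Hz)."""

    psd: np.ndarray
    bin_freqs: np.ndarray
    trial_id: str = ""
    n_segments: int = 0

    def __post_init__(self):
        self.psd = np.asarray(self.psd, dtype=float)
        self.bin_freqs = np.asarray(self.bin_freqs, dtype=float)
        if self.psd.ndim != 2 or self.psd.shape[1] != len(self.bin_freqs):
            raise ValueError("psd must be n_channels x n_bins")
        if np.any(np.diff(self.bin_freqs) <= 0):
            raise ValueError("bin frequencies must be ascending")


@dataclass
class ScalerParams:
    """Per-feature median and IQR over the flattened (channel, bin) axis.

    Quartiles use linear interpolation between order statistics; an IQR of
    exactly zero is replaced by 1 so constant features map to 0.
    """

    median: np.ndarray
    iqr: np.ndarray

    def __post_init__(self):
        self.median = np.asarray(self.median, dtype=float)
        self.iqr = np.asarray(self.iqr, dtype=float)
        if self.median.shape != self.iqr.shape:
            raise ValueError("median/iqr shape mismatch")
        if np.any(self.iqr < 0):
            raise ValueError("iqr must be >= 0")


def bandpass(signal: np.ndarray, fs: float,
             spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase Butterworth bandpass over the sample axis.

    Forward-backward application removes phase distortion and squares the
    magnitude response; DC and out-of-band components are attenuated per
    the squared Butterworth response.
    """
    if fs <= 2 * spec.high_cut:
        raise ValueError(
            f"fs={fs} must exceed twice the high cut-off {spec.high_cut}")
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] <= 3 * (2 * spec.order + 1):
        raise ValueError("signal too short for stable forward-backward filtering")
    sos = scipy.signal.butter(spec.order, [spec.low_cut, spec.high_cut],
                              btype="bandpass", fs=fs, output="sos")
    # the 0.5 Hz corner rings slowly; pad well beyond scipy's default
    # (0.2 / low_cut seconds, capped at n-1)
    padlen = min(signal.shape[-1] - 1, int(0.2 * fs / spec.low_cut))
    return scipy.signal.sosfiltfilt(sos, signal, axis=-1, padlen=padlen)


def downsample(signal: np.ndarray, factor: int = DOWNSAMPLE_FACTOR) -> np.ndarray:
    """Keep every ``factor``-th sample starting at index 0.

    The caller is responsible for prior band-limiting (the 100 Hz cut-off
    leaves all power far below the post-decimation Nyquist).  Output length
    is ``floor(n / factor)``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    signal = np.asarray(signal)
    n = signal.shape[-1]
    l = n // factor
    return signal[..., : l * factor: factor]


def welch_psd(signal: np.ndarray, fs: float = 1000.0,
              trial_id: str = "") -> SpectralFeatures:
    """Welch PSD per channel: 256-point Hann segments, 50% overlap,
    one-sided density (power per Hz)."""
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[-1]
    if n < NPERSEG:
        raise ValueError(f"need >= {NPERSEG} samples, got {n}")
    freqs, psd = scipy.signal.welch(
        signal, fs=fs, window="hann", nperseg=NPERSEG, noverlap=NOVERLAP,
        detrend=False, scaling="density", axis=-1)
    n_segments = (n - NPERSEG) // (NPERSEG - NOVERLAP) + 1
    return SpectralFeatures(psd=np.atleast_2d(psd), bin_freqs=freqs,
                            trial_id=trial_id, n_segments=n_segments)


def featurize_trial(trial: TrialRecording,
                    spec: FilterSpec = FilterSpec(),
                    factor: int = DOWNSAMPLE_FACTOR) -> SpectralFeatures:
    """Full chain bandpass -> downsample -> Welch for one trial."""
    filtered = bandpass(trial.signal, trial.fs, spec)
    low = downsample(filtered, factor)
    return welch_psd(low, fs=trial.fs / factor, trial_id=trial.trial_id)


def _stack(features) -> np.ndarray:
    if isinstance(features, np.ndarray):
        mats = features
    else:
        mats = np.stack([f.psd if isinstance(f, SpectralFeatures) else f
                         for f in features])
    if mats.ndim != 3:
        raise ValueError("expected a collection of channel x bin matrices")
    return mats.reshape(mats.shape[0], -1)


def fit_scaler(train_features) -> ScalerParams:
    """Fit per-feature median/IQR on training trials only."""
    flat = _stack(train_features)
    if flat.shape[0] < 2:
        raise ValueError("need at least 2 training trials to fit the scaler")
    median = np.median(flat, axis=0)
    q1, q3 = np.percentile(flat, [25, 75], axis=0)
    iqr = q3 - q1
    iqr[iqr == 0] = 1.0
    return ScalerParams(median=median, iqr=iqr)


def apply_scaler(features, params: ScalerParams):
    """Scale features to ``(x - median) / iqr``; shape is preserved."""
    if isinstance(features, SpectralFeatures):
        flat = (features.psd.reshape(-1) - params.median) / params.iqr
        return SpectralFeatures(psd=flat.reshape(features.psd.shape),
                                bin_freqs=features.bin_freqs,
                                trial_id=features.trial_id,
                                n_segments=features.n_segments)
    mats = features if isinstance(features, np.ndarray) else np.stack(
        [f.psd if isinstance(f, SpectralFeatures) else f for f in features])
    shape = mats.shape
    flat = (mats.reshape(shape[0], -1) - params.median) / params.iqr
    return flat.reshape(shape)
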