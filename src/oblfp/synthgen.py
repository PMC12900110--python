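"""Synthetic multichannel LFP trial generator.

Emulates the statistical structure the decoder assumes about
olfactory-bulb recordings, so the full pipeline is testable without any
download:

* a 1/f^beta broadband background, generated by frequency-domain amplitude
  shaping of white noise, independent per channel;
* a common low-frequency respiration sinusoid shared across channels
  (volume conduction), randomly phased per trial;
* odor trials additionally carry band-limited noise power centred on an
  odorant-specific frequency band, scaled per channel by a loading vector
  and across concentrations by a saturating Hill dose-response curve.

Every trial is generated from its own counter-derived random substream, so
trial ``i`` of a layout is reproducible in isolation — in particular, a
subset of trials selected after class balancing can be generated without
materializing the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import CONTROL_NAME, TrialRecording, TrialSet

__all__ = [
    "OdorEffectSpec",
    "SynthConfig",
    "MainLayout",
    "ConcentrationLayout",
    "InvalidConfigError",
    "InvalidLayoutError",
    "dose_gain",
    "default_odor_effects",
    "trial_plan",
    "make_trial",
    "iter_trials",
    "gen_background",
    "gen_trialset",
]

N_SUBJECTS = 7


class InvalidConfigError(ValueError):
    pass


class InvalidLayoutError(ValueError):
    pass


@dataclass
class OdorEffectSpec:
    """Spectral fingerprint of one odorant.

    The odor response is extra band-limited power: a Gaussian envelope
    ``exp(-((f - band_center) / band_halfwidth)^2 / 2)`` on the amplitude
    spectrum, multiplied per channel by ``channel_loading`` and across
    concentrations by a Hill gain (see :func:`dose_gain`).
    """

    band_center: float
    band_halfwidth: float
    max_gain: float
    hill_k: float = 0.3
    hill_h: float = 2.0
    channel_loading: np.ndarray | None = None

    def __post_init__(self):
        if self.max_gain < 0:
            raise InvalidConfigError("max_gain must be >= 0")
        if self.hill_k <= 0 or self.hill_h <= 0:
            raise InvalidConfigError("Hill parameters must be positive")
        if self.band_center + self.band_halfwidth > 100.0:
            raise InvalidConfigError(
                "odor band must lie inside the 0.5-100 Hz analysis band")
        if self.channel_loading is not None:
            self.channel_loading = np.asarray(self.channel_loading, dtype=float)
            if np.any((self.channel_loading < 0) | (self.channel_loading > 1)):
                raise InvalidConfigError("channel_loading must lie in [0, 1]")

    def loading(self, n_channels: int) -> np.ndarray:
        if self.channel_loading is None:
            # smooth dorsal-ventral gradient across the probe
            return np.linspace(0.4, 1.0, n_channels)
        if len(self.channel_loading) != n_channels:
            raise InvalidConfigError(
                f"channel_loading length {len(self.channel_loading)} != "
                f"channel count {n_channels}")
        return self.channel_loading


def dose_gain(spec: OdorEffectSpec, concentration: float) -> float:
    """Hill dose-response power multiplier.

    ``1 + max_gain * c^h / (c^h + k^h)``: equals 1 at zero concentration,
    is strictly increasing, and saturates at ``1 + max_gain``.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0 (% v/v)")
    if concentration == 0:
        return 1.0
    ch = concentration ** spec.hill_h
    return 1.0 + spec.max_gain * ch / (ch + spec.hill_k ** spec.hill_h)


def default_odor_effects() -> dict[str, OdorEffectSpec]:
    """Study-condition odorant panel: six odorants with distinct bands and
    effect sizes spanning strong (hexanal) to weak (ethyl acetate)."""
    return {
        "hexanal": OdorEffectSpec(70.0, 15.0, 8.0),
        "2-hexanone": OdorEffectSpec(60.0, 12.0, 7.0),
        "ethyl butyrate": OdorEffectSpec(40.0, 10.0, 6.0),
        "isoamyl acetate": OdorEffectSpec(30.0, 8.0, 5.0),
        "ethyl tiglate": OdorEffectSpec(20.0, 6.0, 3.5),
        "ethyl acetate": OdorEffectSpec(12.0, 5.0, 1.2),
    }


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the canonical recording
    conditions (32 channels at 30 kHz, 2-s trials)."""

    n_channels: int = 32
    fs: float = 30000.0
    duration: float = 2.0
    background_exponent: float = 2.0
    respiration_freq: float = 3.0
    respiration_amp: float = 50.0
    noise_sd: float = 100.0
    odor_effects: dict[str, OdorEffectSpec] = field(default_factory=default_odor_effects)
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.duration <= 0:
            raise InvalidConfigError("fs and duration must be positive")
        if self.background_exponent < 0:
            raise InvalidConfigError("background exponent must be >= 0")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise InvalidConfigError("fs * duration must be an integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


# ---------------------------------------------------------------------------
# experiment layouts


@dataclass
class MainLayout:
    """Six odorants at one concentration plus mineral-oil controls
    (2013 odor-presence + 336 control trials by default)."""

    odor_counts: dict[str, int] = field(default_factory=lambda: {
        "hexanal": 337,
        "2-hexanone": 335,
        "ethyl butyrate": 335,
        "isoamyl acetate": 336,
        "ethyl tiglate": 335,
        "ethyl acetate": 335,
    })
    control_count: int = 336
    concentration: float = 0.3


@dataclass
class ConcentrationLayout:
    """One odorant across a concentration ladder plus controls
    (4 x 200 + 200 = 1000 trials by default)."""

    odorant: str = "ethyl butyrate"
    concentrations: tuple[float, ...] = (0.03, 0.1, 0.3, 1.0)
    n_per_level: int = 200
    control_count: int = 200


def trial_plan(layout: MainLayout | ConcentrationLayout) -> pd.DataFrame:
    """Expand a layout into a per-trial metadata table.

    Columns: trial_id, gen_index (the substream counter), odorant,
    concentration, subject.  Subjects are assigned round-robin.
    """
    rows: list[tuple[str, float]] = []
    if isinstance(layout, MainLayout):
        for name, count in layout.odor_counts.items():
            rows.extend((name, layout.concentration) for _ in range(count))
        rows.extend((CONTROL_NAME, 0.0) for _ in range(layout.control_count))
    elif isinstance(layout, ConcentrationLayout):
        for conc in layout.concentrations:
            rows.extend((layout.odorant, conc) for _ in range(layout.n_per_level))
        rows.extend((CONTROL_NAME, 0.0) for _ in range(layout.control_count))
    else:
        raise InvalidLayoutError(f"unknown layout type {type(layout).__name__}")
    n = len(rows)
    width = max(4, len(str(max(n - 1, 0))))
    return pd.DataFrame({
        "trial_id": [f"trial-{i:0{width}d}" for i in range(n)],
        "gen_index": np.arange(n),
        "odorant": [r[0] for r in rows],
        "concentration": [r[1] for r in rows],
        "subject": [f"mouse-{i % N_SUBJECTS}" for i in range(n)],
    })


# ---------------------------------------------------------------------------
# signal synthesis


def _background_shape(config: SynthConfig, freqs: np.ndarray) -> np.ndarray:
    """Amplitude-spectrum shaping ``f^(-beta/2)``, unit mean power, zero DC."""
    shape = np.zeros_like(freqs)
    pos = freqs > 0
    # clamp below 0.1 Hz so the 1/f divergence stays finite
    f = np.maximum(freqs[pos], 0.1)
    shape[pos] = f ** (-config.background_exponent / 2.0)
    n = len(freqs)
    # normalize so the shaped white noise keeps unit variance
    power = shape ** 2
    mean_power = (power.sum() * 2 - power[0] - (power[-1] if n % 2 else 0)) / max(
        2 * (n - 1), 1)
    if mean_power > 0:
        shape /= np.sqrt(mean_power)
    return shape


def _shaped_noise(rng: np.random.Generator, config: SynthConfig,
                  envelope: np.ndarray) -> np.ndarray:
    """White noise per channel, amplitude-shaped by ``envelope`` in the
    frequency domain; unit variance when the envelope has unit mean power."""
    n = config.n_samples
    white = rng.standard_normal((config.n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    spec *= envelope[None, :]
    return np.fft.irfft(spec, n=n, axis=1)


def make_trial(config: SynthConfig, gen_index: int, trial_id: str,
               odorant: str, concentration: float, subject: str) -> TrialRecording:
    """Generate one trial from its counter-derived substream."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(int(gen_index),)))
    n = config.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs)
    bg_shape = _background_shape(config, freqs)

    signal = config.noise_sd * _shaped_noise(rng, config, bg_shape)

    # respiration: one sinusoid shared across channels, per-channel scale
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / config.fs
    resp = np.sin(2 * np.pi * config.respiration_freq * t + phase)
    resp_scale = np.linspace(0.7, 1.0, config.n_channels)
    signal += config.respiration_amp * resp_scale[:, None] * resp[None, :]

    if odorant != CONTROL_NAME:
        if odorant not in config.odor_effects:
            raise InvalidLayoutError(f"unknown odorant '{odorant}' in layout")
        spec = config.odor_effects[odorant]
        gain = dose_gain(spec, concentration)
        if gain > 1.0:
            envelope = np.exp(-0.5 * ((freqs - spec.band_center)
                                      / spec.band_halfwidth) ** 2)
            band = _shaped_noise(rng, config, bg_shape * envelope * np.sqrt(gain - 1.0))
            loading = spec.loading(config.n_channels)
            signal += config.noise_sd * loading[:, None] * band

    return TrialRecording(
        trial_id=trial_id,
        signal=signal,
        fs=config.fs,
        odorant_name=odorant,
        concentration=concentration,
        subject_id=subject,
    )


def iter_trials(config: SynthConfig, plan: pd.DataFrame):
    """Yield trials of a plan one at a time (constant memory)."""
    for row in plan.itertuples(index=False):
        yield make_trial(config, row.gen_index, row.trial_id,
                         row.odorant, row.concentration, row.subject)


def gen_background(config: SynthConfig, n_trials: int) -> TrialSet:
    """Generate odor-absence (mineral-oil control) trials only."""
    if n_trials < 1:
        raise InvalidConfigError("n_trials must be >= 1")
    plan = trial_plan(MainLayout(odor_counts={}, control_count=n_trials))
    return gen_trialset(config, plan)


def gen_trialset(config: SynthConfig,
                 layout: MainLayout | ConcentrationLayout | pd.DataFrame) -> TrialSet:
    """Generate the full trial set for a layout (or a pre-built plan).

    A plan subset (for example the survivors of class balancing) generates
    the exact same signals as the corresponding rows of the full layout.
    """
    plan = layout if isinstance(layout, pd.DataFrame) else trial_plan(layout)
    unknown = set(plan["odorant"]) - set(config.odor_effects) - {CONTROL_NAME}
    if unknown:
        raise InvalidLayoutError(f"unknown odorants in layout: {sorted(unknown)}")
    return TrialSet(list(iter_trials(config, plan)))
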