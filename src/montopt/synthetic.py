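"""Synthetic emotion and attention datasets with known ground truth.

The generators emulate the structure of the two source experiments without
any biophysical forward modelling: every channel carries independent
1/f^exponent Gaussian background noise at EEG-like amplitude (~10 uV RMS),
class- or state-dependent signal is added as band-limited Gaussian noise
(realistic spectra, no pure sinusoids) at chosen electrodes, and eye
blinks are injected on frontal channels as biphasic 100-300 uV transients
at Poisson times with positions recorded as ground truth.

Emotion sessions: trials of four valence-arousal classes whose band power
at the signal electrodes is scaled per class.  Attention sessions: a slow
latent attention drift (smoothed random walk in [0, 1]) modulates both the
per-trial probability of a correct response and the band power at the
coupled electrodes, so the behavioral CONC index and the EEG co-vary.

Default sizes are the desk-scale profile (128 Hz, 8 subjects, 40 x 10-s
emotion trials, 400 attention trials) so an exhaustive 2-electrode montage
search runs in minutes; ``full_scale()`` mirrors the source experiments
(512 Hz, 60-s trials, 1316 trials).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .attention_eval import AttentionSubjectData, BehavioralStream
from .features import BandDefinition, DEFAULT_BANDS
from .montage import default_montage
from .preprocess import RawRecording

__all__ = [
    "EmotionSimSpec",
    "AttentionSimSpec",
    "gen_background",
    "gen_emotion_dataset",
    "gen_attention_dataset",
]

_CLASSES = ("HAHV", "HALV", "LAHV", "LALV")

#: Per-class band-power multipliers at the signal electrodes: the four
#: valence-arousal quadrants differ in alpha power and its lateralization
#: (left-frontal vs right-frontal alpha asymmetry is the classic valence
#: marker), giving four linearly separable spectral signatures.
_DEFAULT_EFFECT: dict[str, dict[str, dict[str, float]]] = {
    "HAHV": {"F7": {"alpha": 3.0}, "F8": {"alpha": 3.0}},
    "HALV": {"F7": {"alpha": 3.0}},
    "LAHV": {"F8": {"alpha": 3.0}},
    "LALV": {},
}

_BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}


@dataclass(frozen=True)
class EmotionSimSpec:
    """Desk-scale emulation of a 4-class emotion-elicitation session."""

    n_subjects: int = 8
    n_trials_per_class: int = 10
    trial_s: float = 10.0
    fs: float = 128.0
    signal_channels: tuple[str, ...] = ("F7", "F8")
    effect: dict = field(default_factory=lambda: _DEFAULT_EFFECT)
    noise_exponent: float = 1.0
    noise_uv: float = 10.0
    blink_rate_per_min: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for cls, per_ch in self.effect.items():
            for ch, per_band in per_ch.items():
                for band, mult in per_band.items():
                    if mult <= 0:
                        raise ValueError(f"multiplier for {cls}/{ch}/{band} must be > 0")

    @classmethod
    def full_scale(cls, **kw) -> "EmotionSimSpec":
        """Source-experiment sizes: 512 Hz, 60-s trials."""
        return cls(**{"fs": 512.0, "trial_s": 60.0, **kw})


def _default_accuracy_link(drift: np.ndarray) -> np.ndarray:
    return 0.25 + 0.65 * drift


@dataclass(frozen=True)
class AttentionSimSpec:
    """Desk-scale emulation of a d2-style sustained-attention session."""

    n_subjects: int = 8
    n_trials: int = 400
    trial_s: float = 0.5
    fs: float = 128.0
    target_frac: float = 0.45
    coupling_channels: tuple[str, ...] = ("Fz", "Pz")
    coupling_band: str = "alpha"
    coupling_strength: float = 2.0
    #: Attention redistributes band power between the coupled sites (the
    #: anterior-posterior alpha shift with vigilance): even-indexed coupling
    #: channels scale with the drift, odd-indexed ones with (1 - drift).
    #: With False, all coupled channels scale with the drift identically.
    coupling_redistribute: bool = True
    drift_smooth_trials: float = 60.0
    accuracy_link: Callable[[np.ndarray], np.ndarray] = _default_accuracy_link
    noise_exponent: float = 1.0
    noise_uv: float = 10.0
    blink_rate_per_min: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_frac < 1:
            raise ValueError("target_frac must be in (0, 1)")
        if self.coupling_strength < 0:
            raise ValueError("coupling strength must be >= 0")

    @classmethod
    def full_scale(cls, **kw) -> "AttentionSimSpec":
        """Source-experiment sizes: 1316 trials at 512 Hz."""
        return cls(**{"fs": 512.0, "n_trials": 1316, **kw})


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int, fs: float, exponent: float) -> np.ndarray:
    """Independent 1/f^exponent Gaussian noise per channel, unit variance."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n=n_samp, axis=1)
    sd = x.std(axis=1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def gen_background(
    channels: Sequence[str],
    duration_s: float,
    fs: float,
    exponent: float = 1.0,
    seed: int | np.random.Generator = 0,
    amplitude_uv: float = 10.0,
) -> RawRecording:
    """Continuous 1/f^exponent background EEG, ``amplitude_uv`` RMS per channel."""
    if not 0 <= exponent <= 2:
        raise ValueError("spectral exponent must be in [0, 2]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    data = amplitude_uv * _pink_noise(rng, len(channels), n, fs, exponent)
    return RawRecording(data=data, fs=fs, labels=tuple(channels))


def _band_limited(rng: np.random.Generator, n_samp: int, fs: float, band: BandDefinition) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise (FFT brick-wall shaping)."""
    white = rng.standard_normal(n_samp)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    mask = (freqs >= band.low_hz) & (freqs < band.high_hz)
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n_samp)
    sd = x.std()
    return x / (sd if sd > 0 else 1.0)


def _band_rms(fs: float, exponent: float, band: BandDefinition, amplitude_uv: float) -> float:
    """RMS of the background inside a band (from the 1/f^exponent shape)."""
    n = 4096
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)[1:]
    power = freqs**-exponent
    power /= power.sum()
    in_band = (freqs >= band.low_hz) & (freqs < band.high_hz)
    return amplitude_uv * float(np.sqrt(power[in_band].sum()))


_BLINK_CHANNELS = {"fp1": 1.0, "fp2": 1.0, "af3": 0.7, "af4": 0.7}


def _inject_blinks(
    rng: np.random.Generator,
    data: np.ndarray,
    labels: Sequence[str],
    fs: float,
    rate_per_min: float,
) -> list[int]:
    """Add biphasic frontal blink transients at Poisson times; return onsets."""
    if rate_per_min <= 0:
        return []
    n = data.shape[1]
    dur = int(round(0.3 * fs))
    half = dur // 2
    t = np.arange(dur)
    up = np.sin(np.pi * t[:half] / half) ** 2
    down = -0.5 * np.sin(np.pi * (t[half:] - half) / (dur - half)) ** 2
    shape = np.concatenate([up, down])
    idx = {c.strip().lower(): i for i, c in enumerate(labels)}
    onsets: list[int] = []
    n_blinks = rng.poisson(rate_per_min * (n / fs) / 60.0)
    for _ in range(n_blinks):
        start = int(rng.integers(0, max(n - dur, 1)))
        amp = float(rng.uniform(100.0, 300.0))
        for ch, gain in _BLINK_CHANNELS.items():
            if ch in idx:
                data[idx[ch], start : start + dur] += amp * gain * shape[: n - start]
        onsets.append(start)
    return sorted(onsets)


def gen_emotion_dataset(spec: EmotionSimSpec = EmotionSimSpec()):
    """Per-subject ``(RawRecording, blink_onsets)`` with per-trial class labels.

    Each subject's recording holds ``4 * n_trials_per_class`` trials in a
    seeded random order (``trial_bounds`` and ``trial_labels`` populated).
    Class signal is band-limited noise added at the signal electrodes so
    the band power is scaled by the class multiplier; blink ground-truth
    onsets are returned per subject.
    """
    rng = np.random.default_rng(spec.rng_seed)
    montage = default_montage()
    labels = montage.all_channels
    trial_n = int(round(spec.trial_s * spec.fs))
    out = []
    for si in range(spec.n_subjects):
        classes = np.repeat(_CLASSES, spec.n_trials_per_class)
        rng.shuffle(classes)
        n_total = trial_n * len(classes)
        data = spec.noise_uv * _pink_noise(rng, len(labels), n_total, spec.fs, spec.noise_exponent)
        ch_pos = {c.strip().lower(): i for i, c in enumerate(labels)}
        for t, cls in enumerate(classes):
            s = t * trial_n
            for ch, per_band in spec.effect.get(cls, {}).items():
                for band_name, mult in per_band.items():
                    band = _BAND_BY_NAME[band_name]
                    base = _band_rms(spec.fs, spec.noise_exponent, band, spec.noise_uv)
                    add_rms = base * np.sqrt(max(mult - 1.0, 0.0))
                    if add_rms == 0:
                        continue
                    data[ch_pos[ch.strip().lower()], s : s + trial_n] += (
                        add_rms * _band_limited(rng, trial_n, spec.fs, band)
                    )
        blinks = _inject_blinks(rng, data, labels, spec.fs, spec.blink_rate_per_min)
        rec = RawRecording(
            data=data, fs=spec.fs, labels=labels,
            trial_bounds=[(t * trial_n, (t + 1) * trial_n) for t in range(len(classes))],
            trial_labels=list(classes),
        )
        out.append((rec, blinks))
    return out


def gen_attention_dataset(spec: AttentionSimSpec = AttentionSimSpec()):
    """Per-subject ``AttentionSubjectData`` plus the latent drift ground truth.

    Returns a list of ``(AttentionSubjectData, drift)`` tuples.  The drift
    is a smoothed random walk normalized to [0, 1]; per-trial correctness
    is Bernoulli(accuracy_link(drift)) and the coupled electrodes' band
    power is scaled by ``1 + coupling_strength * drift``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    montage = default_montage()
    labels = montage.all_channels
    trial_n = int(round(spec.trial_s * spec.fs))
    band = _BAND_BY_NAME[spec.coupling_band]
    out = []
    for si in range(spec.n_subjects):
        walk = np.cumsum(rng.standard_normal(spec.n_trials))
        drift = gaussian_filter1d(walk, spec.drift_smooth_trials)
        span = drift.max() - drift.min()
        drift = (drift - drift.min()) / (span if span > 0 else 1.0)

        p_correct = np.clip(spec.accuracy_link(drift), 0.0, 1.0)
        is_target = rng.random(spec.n_trials) < spec.target_frac
        correct = rng.random(spec.n_trials) < p_correct
        stream = BehavioralStream(is_target=is_target, correct=correct)

        n_total = trial_n * spec.n_trials
        data = spec.noise_uv * _pink_noise(rng, len(labels), n_total, spec.fs, spec.noise_exponent)
        base = _band_rms(spec.fs, spec.noise_exponent, band, spec.noise_uv)
        ch_pos = {c.strip().lower(): i for i, c in enumerate(labels)}
        for j, ch in enumerate(spec.coupling_channels):
            comp = _band_limited(rng, n_total, spec.fs, band)
            d_ch = drift if (j % 2 == 0 or not spec.coupling_redistribute) else 1.0 - drift
            gain = np.sqrt(np.repeat(spec.coupling_strength * d_ch, trial_n)) * base
            data[ch_pos[ch.strip().lower()]] += gain * comp
        blinks = _inject_blinks(rng, data, labels, spec.fs, spec.blink_rate_per_min)
        rec = RawRecording(
            data=data, fs=spec.fs, labels=labels,
            trial_bounds=[(t * trial_n, (t + 1) * trial_n) for t in range(spec.n_trials)],
        )
        keep = np.ones(spec.n_trials, dtype=bool)
        if blinks:
            blink_trials = {min(b // trial_n, spec.n_trials - 1) for b in blinks}
            keep[list(blink_trials)] = False
        subj = AttentionSubjectData(rec=rec, stream=stream, keep_mask=keep, subject_id=f"s{si}")
        out.append((subj, drift))
    return out
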