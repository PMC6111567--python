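"""Seeded generator of DEAP-like EEG trials with rating-driven spectra.

Each generated trial mimics the preprocessed form of the benchmark
recordings: 128 Hz sampling, content band-limited to 4-45 Hz, a 3 s
baseline followed by 60 s of signal, and the 22-electrode montage.  The
per-channel signal is a sum of

* band-limited 1/f^e background noise (the broadband EEG floor), and
* amplitude-modulated narrowband oscillations in the theta (4-8 Hz),
  alpha (8-13 Hz) and beta (13-30 Hz) bands.  The slow random modulation
  makes segments genuinely nonstationary, so time-frequency descriptors
  carry information that a static spectrum would not.

Emotion effects enter multiplicatively on band amplitudes:

* arousal scales the beta-band amplitude by exp(arousal_effect * (A - 5)),
  so beta power is monotone in the arousal rating;
* valence induces an alpha left/right asymmetry: right-hemisphere channels
  are scaled by exp(+valence_effect * (V - 5)) and left-hemisphere channels
  by the reciprocal, so the asymmetry is monotone in the valence rating.

Ratings are drawn by a class-balance schedule.  The default ``balanced``
schedule cycles through the class regions of a requested labeling scheme
(by default the five regions of the five-class scheme: four quadrant
corners plus the central neutral box) and samples uniformly inside each,
guaranteeing every class is populated and balanced up to rounding;
``uniform`` samples uniformly over the whole [1, 9]^2 plane.

All randomness derives from a single integer seed; each (subject, trial)
pair gets its own child stream, so any trial regenerates identically
regardless of generation order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from . import labeling as _labeling
from .io_dataset import Trial, write_dataset, _C4_CHANNELS

__all__ = ["SynthConfig", "generate_trial", "sample_ratings", "generate_dataset", "is_left_channel"]

_BANDS = {"theta": (4.5, 7.5), "alpha": (9.0, 12.0), "beta": (15.0, 28.0)}
# Oscillation amplitudes relative to the unit-variance background; chosen so
# each rhythm's power is comparable to the background power inside its own
# band, making the rating-driven gains recoverable but not trivial.
_BASE_AMPLITUDE = {"theta": 0.6, "alpha": 1.0, "beta": 1.0}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic dataset.

    Defaults mirror the benchmark's preprocessed recordings (32 subjects x
    40 trials of 3 + 60 s at 128 Hz on the 22-channel montage).  The effect
    sizes are log-amplitude gains per rating unit away from the scale
    midpoint; the default arousal effect of 0.2 gives roughly a 2.5x total
    beta-band power ratio between arousal 8 and 2, a deliberately clear but
    band-limited class signal.
    """

    n_subjects: int = 32
    trials_per_subject: int = 40
    fs: float = 128.0
    duration_s: float = 60.0
    baseline_s: float = 3.0
    channels: tuple[str, ...] = _C4_CHANNELS
    arousal_effect: float = 0.2
    valence_effect: float = 0.15
    noise_exponent: float = 1.0
    seed: int = 0
    balance: str = "balanced"
    scheme: str = "2D-5CLS"

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0 or self.baseline_s < 0:
            raise ValueError("durations and sampling rate must be positive")
        if self.arousal_effect < 0 or self.valence_effect < 0:
            raise ValueError("effect sizes must be nonnegative")
        unknown = set(self.channels) - set(_C4_CHANNELS)
        if unknown:
            raise ValueError(f"channels outside the montage: {sorted(unknown)}")
        if self.balance not in ("balanced", "uniform"):
            raise ValueError("balance must be 'balanced' or 'uniform'")
        _labeling.label_scheme(self.scheme)  # validate the name


def is_left_channel(name: str) -> bool:
    """Left-hemisphere electrodes carry odd position numbers (F3, T7, ...)."""
    digits = "".join(ch for ch in name if ch.isdigit())
    if not digits:
        raise ValueError(f"midline channel {name!r} has no hemisphere")
    return int(digits) % 2 == 1


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float, exponent: float) -> np.ndarray:
    """1/f^exponent power noise, band-limited to 4-45 Hz, unit variance."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amplitude = np.zeros_like(freqs)
    band = (freqs >= 4.0) & (freqs <= 45.0)
    amplitude[band] = freqs[band] ** (-exponent / 2.0)
    spectrum = amplitude * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spectrum, n=n)
    return x / x.std()


def _am_oscillation(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Amplitude-modulated sinusoid with a random carrier inside ``band``.

    The modulation rate (0.1-0.4 Hz) keeps sidebands well inside the 4-45 Hz
    band while making the envelope, hence the segment statistics, vary over
    the 4 s analysis windows.
    """
    t = np.arange(n) / fs
    carrier = rng.uniform(*band)
    phase = rng.uniform(0, 2 * np.pi)
    mod_rate = rng.uniform(0.1, 0.4)
    mod_phase = rng.uniform(0, 2 * np.pi)
    envelope = 0.5 * (1.0 + np.sin(2 * np.pi * mod_rate * t + mod_phase))
    return envelope * np.sin(2 * np.pi * carrier * t + phase)


def generate_trial(
    ratings: tuple[float, float],
    config: SynthConfig,
    rng: np.random.Generator,
    subject_id: str = "s01",
    trial_id: str = "t01",
) -> Trial:
    """Generate one trial whose band structure encodes the rating pair."""
    arousal, valence = (float(r) for r in ratings)
    if not (1.0 <= arousal <= 9.0 and 1.0 <= valence <= 9.0):
        raise ValueError(f"ratings ({arousal}, {valence}) outside the [1, 9] scale")
    n = int(round((config.baseline_s + config.duration_s) * config.fs))
    beta_gain = np.exp(config.arousal_effect * (arousal - 5.0))
    asym = config.valence_effect * (valence - 5.0)
    signal = np.empty((len(config.channels), n))
    for i, name in enumerate(config.channels):
        x = _band_limited_noise(rng, n, config.fs, config.noise_exponent)
        for band_name, band in _BANDS.items():
            amp = _BASE_AMPLITUDE[band_name]
            if band_name == "beta":
                amp *= beta_gain
            elif band_name == "alpha":
                amp *= np.exp(-asym if is_left_channel(name) else asym)
            x = x + amp * _am_oscillation(rng, n, config.fs, band)
        signal[i] = x
    return Trial(
        subject_id=subject_id,
        trial_id=trial_id,
        signal=signal,
        fs=config.fs,
        channel_names=config.channels,
        arousal=arousal,
        valence=valence,
        baseline_seconds=config.baseline_s,
    )


# Archetypal rating region (arousal range, valence range) of every class.
# High/low bands follow the outer closed intervals of the three-level scheme
# ([6.5, 9] / [1, 3.5]); the neutral box sits strictly inside the open
# (3.5, 6.5) interval.  Cycling over a scheme's class regions balances that
# scheme's classes and gives every class unambiguous exemplars.
_CLASS_REGIONS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "HA": ((6.5, 9.0), (1.0, 9.0)),
    "LA": ((1.0, 3.5), (1.0, 9.0)),
    "HV": ((1.0, 9.0), (6.5, 9.0)),
    "LV": ((1.0, 9.0), (1.0, 3.5)),
    "HAHV": ((6.5, 9.0), (6.5, 9.0)),
    "LAHV": ((1.0, 3.5), (6.5, 9.0)),
    "LALV": ((1.0, 3.5), (1.0, 3.5)),
    "HALV": ((6.5, 9.0), (1.0, 3.5)),
    "neutral": ((3.6, 6.4), (3.6, 6.4)),
}


def sample_ratings(
    n: int,
    rng: np.random.Generator,
    balance: str = "balanced",
    scheme: str = "2D-5CLS",
) -> np.ndarray:
    """Draw ``n`` (arousal, valence) pairs per the balance schedule.

    ``balanced`` cycles over the classes of ``scheme`` and samples uniformly
    inside each class's archetypal region, so all of that scheme's classes
    are populated (and balanced up to rounding) once ``n`` reaches the class
    count; ``uniform`` draws from the whole [1, 9]^2 plane.
    """
    if balance == "uniform":
        return rng.uniform(1.0, 9.0, size=(n, 2))
    classes = _labeling.label_scheme(scheme).classes
    out = np.empty((n, 2))
    for i in range(n):
        (a_lo, a_hi), (v_lo, v_hi) = _CLASS_REGIONS[classes[i % len(classes)]]
        out[i] = (rng.uniform(a_lo, a_hi), rng.uniform(v_lo, v_hi))
    return out


def generate_dataset(config: SynthConfig, out_dir: str | os.PathLike | None = None) -> list[Trial]:
    """Generate the full dataset; optionally write it in the directory layout."""
    trials: list[Trial] = []
    for s in range(config.n_subjects):
        subject_id = f"s{s + 1:02d}"
        ratings_rng = np.random.default_rng([config.seed, s, 2**20])
        ratings = sample_ratings(
            config.trials_per_subject, ratings_rng, config.balance, config.scheme
        )
        for t in range(config.trials_per_subject):
            rng = np.random.default_rng([config.seed, s, t])
            trials.append(
                generate_trial(
                    tuple(ratings[t]), config, rng,
                    subject_id=subject_id, trial_id=f"t{t + 1:02d}",
                )
            )
    if out_dir is not None:
        write_dataset(trials, out_dir)
    return trials
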