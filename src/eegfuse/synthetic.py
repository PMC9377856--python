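"""Synthetic two-class motor-imagery EEG generator.

Motor imagery of one hand attenuates the mu rhythm (8-12 Hz) over the
contralateral sensorimotor cortex — event-related desynchronization (ERD).
The generator emulates exactly that physics on a three-channel C3/Cz/C4
montage: each trial is 1/f background noise plus a random-phase mu
sinusoid whose amplitude at the contralateral electrode is multiplied by
``erd_ratio`` (1.0 = no effect, smaller = stronger desynchronization).
Right-hand trials attenuate C3, left-hand trials attenuate C4 and Cz is
unaffected.

Each trial draws from its own seeded substream, so enlarging the trial
count never reshuffles earlier trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .epochs import EpochSet

__all__ = [
    "SyntheticConfig",
    "generate_mi_epochs",
    "generate_null_epochs",
    "generate_ar_series",
]

_DEFAULT_NAMES = ("C3", "Cz", "C4")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic motor-imagery recording.

    ``snr`` is the ratio of the (unattenuated) mu sinusoid amplitude to the
    background-noise standard deviation; ``erd_ratio`` multiplies the mu
    amplitude at the electrode contralateral to the imagined hand.
    """

    n_trials_per_class: int
    n_channels: int = 3
    fs: float = 250.0
    epoch_length: float = 4.0
    mu_freq: float = 10.0
    erd_ratio: float = 0.4
    noise_exponent: float = 1.0
    snr: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_class < 1:
            raise ValueError(
                f"n_trials_per_class must be >= 1, got {self.n_trials_per_class}"
            )
        if self.n_channels < 1:
            raise ValueError(f"n_channels must be >= 1, got {self.n_channels}")
        if not 0.0 <= self.erd_ratio <= 1.0:
            raise ValueError(f"erd_ratio must lie in [0, 1], got {self.erd_ratio}")
        if not self.fs > 2 * self.mu_freq:
            raise ValueError(
                f"fs must exceed twice mu_freq ({self.fs} <= 2*{self.mu_freq})"
            )
        if self.epoch_length <= 0:
            raise ValueError(f"epoch_length must be positive, got {self.epoch_length}")
        if self.snr < 0:
            raise ValueError(f"snr must be non-negative, got {self.snr}")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.epoch_length))

    @property
    def channel_names(self) -> tuple[str, ...]:
        if self.n_channels <= 3:
            return _DEFAULT_NAMES[: self.n_channels]
        extra = tuple(f"EEG{i}" for i in range(4, self.n_channels + 1))
        return _DEFAULT_NAMES + extra


def _colored_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _trial_rng(seed: int, trial: int) -> np.random.Generator:
    # substream keyed by (seed, trial index): stable under trial-count changes
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(trial,)))


def generate_mi_epochs(config: SyntheticConfig) -> EpochSet:
    """Generate balanced left/right motor-imagery epochs with planted ERD.

    Trials alternate left, right, left, ... Right-hand trials multiply the
    mu amplitude at C3 by ``config.erd_ratio``; left-hand trials do the same
    at C4; all other channels carry the full-amplitude rhythm. Identical
    configs (including seed) produce bit-identical output.
    """
    n_trials = 2 * config.n_trials_per_class
    n = config.n_samples
    names = config.channel_names
    t = np.arange(n) / config.fs
    data = np.empty((n_trials, config.n_channels, n))
    labels = np.empty(n_trials, dtype="<U5")
    for i in range(n_trials):
        label = "left" if i % 2 == 0 else "right"
        labels[i] = label
        rng = _trial_rng(config.seed, i)
        for c, name in enumerate(names):
            noise = _colored_noise(n, config.noise_exponent, rng)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            amp = config.snr
            if (label == "right" and name == "C3") or (label == "left" and name == "C4"):
                amp *= config.erd_ratio
            data[i, c] = noise + amp * np.sin(2.0 * np.pi * config.mu_freq * t + phase)
    return EpochSet(data=data, labels=labels, fs=config.fs, channel_names=names)


def generate_null_epochs(config: SyntheticConfig) -> EpochSet:
    """Epochs with no class-dependent signal (``erd_ratio`` forced to 1).

    The labels are assigned as in :func:`generate_mi_epochs` but carry no
    information; downstream classification should sit at chance level.
    """
    return generate_mi_epochs(replace(config, erd_ratio=1.0))


def generate_ar_series(
    coeffs: tuple[float, ...] | list[float],
    n: int,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate an autoregressive series y(t) = -sum_i a_i y(t-i) + e(t).

    ``coeffs`` are the a_i of the recursion above (note the leading minus
    sign: ``coeffs=(-0.5,)`` gives y(t) = 0.5 y(t-1) + e(t)).  The process
    must be stationary (all poles strictly inside the unit circle).
    """
    a = np.asarray(coeffs, dtype=float)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    denom = np.concatenate(([1.0], a))
    if a.size:
        poles = np.roots(denom)
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError(
                f"non-stationary AR coefficients {tuple(a)}: pole magnitude(s) "
                f"{np.abs(poles).max():.4f} >= 1"
            )
    rng = np.random.default_rng(seed)
    # burn-in lets the recursion forget the zero initial state
    burn = max(10 * a.size, 100)
    e = rng.normal(0.0, noise_sd, size=n + burn)
    y = signal.lfilter([1.0], denom, e)
    return y[burn:]
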