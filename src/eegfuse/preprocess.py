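"""Band-pass preprocessing and channel selection.

The sensorimotor rhythms that motor imagery modulates live in the 8-30 Hz
band, so epochs are band-pass filtered with a Butterworth design (default
8-30 Hz, order 4) before feature extraction.  Filtering is applied
zero-phase (forward-backward) so that the covariance structure seen by the
spatial filters is not distorted by group delay; "order" refers to the
design order handed to the band-pass designer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .epochs import EpochSet

__all__ = ["FilterSpec", "design_bandpass", "apply_filter", "select_channels"]


@dataclass(frozen=True)
class FilterSpec:
    """A designed Butterworth band-pass filter.

    ``sos`` holds the cascaded second-order sections; the -3 dB points of
    the single-pass magnitude response sit at ``low_hz`` and ``high_hz``.
    """

    low_hz: float
    high_hz: float
    order: int
    fs: float
    sos: np.ndarray

    def freq_response(self, freqs_hz: np.ndarray | list[float]) -> np.ndarray:
        """Complex single-pass frequency response H(f) at the given frequencies."""
        freqs_hz = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
        _, h = signal.sosfreqz(self.sos, worN=2 * np.pi * freqs_hz / self.fs)
        return h


def design_bandpass(
    low_hz: float, high_hz: float, order: int = 4, fs: float = 250.0
) -> FilterSpec:
    """Design a Butterworth band-pass filter.

    Raises
    ------
    ValueError
        If the band edges are not ``0 < low < high < fs/2`` or ``order < 1``.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if not 0 < low_hz < high_hz:
        raise ValueError(f"need 0 < low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= fs / 2:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {fs / 2}"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    # all poles strictly inside the unit circle
    _, poles, _ = signal.sos2zpk(sos)
    if np.any(np.abs(poles) >= 1.0):
        raise ValueError("designed filter is unstable")
    return FilterSpec(low_hz=low_hz, high_hz=high_hz, order=order, fs=fs, sos=sos)


def apply_filter(epochs: EpochSet, spec: FilterSpec) -> EpochSet:
    """Zero-phase (forward-backward) filtering of every trial and channel.

    Reflect-padding of one settling length is applied at the epoch edges
    (scipy's default for ``sosfiltfilt``).  The effective magnitude response
    is |H(f)|^2 and the phase response is zero.
    """
    if epochs.fs != spec.fs:
        raise ValueError(
            f"sampling-rate mismatch: epochs at {epochs.fs} Hz, filter designed "
            f"for {spec.fs} Hz"
        )
    filtered = signal.sosfiltfilt(spec.sos, epochs.data, axis=-1)
    return EpochSet(
        data=filtered,
        labels=epochs.labels,
        fs=epochs.fs,
        channel_names=epochs.channel_names,
    )


def _canon(name: str) -> str:
    # the 10-20 literature mixes "CZ" and "Cz"; match case-insensitively
    return name.strip().lower()


def select_channels(epochs: EpochSet, names: tuple[str, ...] | list[str]) -> EpochSet:
    """Subset and reorder channels by name (case-insensitive, CZ == Cz)."""
    lookup = {_canon(n): i for i, n in enumerate(epochs.channel_names)}
    idx = []
    for name in names:
        key = _canon(name)
        if key not in lookup:
            raise ValueError(
                f"unknown channel {name!r}; available: {list(epochs.channel_names)}"
            )
        idx.append(lookup[key])
    if len(set(idx)) != len(idx):
        raise ValueError(f"duplicate channels requested: {list(names)}")
    return EpochSet(
        data=epochs.data[:, idx, :],
        labels=epochs.labels,
        fs=epochs.fs,
        channel_names=tuple(epochs.channel_names[i] for i in idx),
    )
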