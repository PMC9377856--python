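"""Epoched multichannel EEG container.

The :class:`EpochSet` is the universal signal currency of the pipeline: a
``(trials, channels, samples)`` tensor of microvolt-scale values with
per-trial class labels, a sampling rate and an ordered channel list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EpochSet"]


@dataclass(frozen=True)
class EpochSet:
    """Labelled two-class EEG epochs.

    Parameters
    ----------
    data
        Real tensor of shape ``(n_trials, n_channels, n_samples)``.
    labels
        Per-trial class label, length ``n_trials`` (e.g. ``"left"``/``"right"``).
    fs
        Sampling rate in Hz.
    channel_names
        Ordered, unique channel names, length ``n_channels``.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = field(default=("C3", "Cz", "C4"))

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        labels = np.asarray(self.labels)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if data.ndim != 3:
            raise ValueError(
                f"data must be (trials, channels, samples); got shape {data.shape}"
            )
        if labels.shape != (data.shape[0],):
            raise ValueError(
                f"labels length {labels.shape} does not match trial count {data.shape[0]}"
            )
        if len(self.channel_names) != data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {data.shape[1]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel_names must be unique")
        if not np.isfinite(data).all():
            raise ValueError("data contains non-finite samples")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique labels."""
        return np.unique(self.labels)

    def class_indices(self) -> dict[str, np.ndarray]:
        """Trial indices per class, keyed by label."""
        return {str(c): np.flatnonzero(self.labels == c) for c in self.classes}

    def subset(self, trial_idx: np.ndarray) -> "EpochSet":
        """Return a new EpochSet restricted to the given trial indices."""
        trial_idx = np.asarray(trial_idx)
        return EpochSet(
            data=self.data[trial_idx],
            labels=self.labels[trial_idx],
            fs=self.fs,
            channel_names=self.channel_names,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EpochSet):
            return NotImplemented
        return (
            self.fs == other.fs
            and self.channel_names == other.channel_names
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.data, other.data)
        )
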