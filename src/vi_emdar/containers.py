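"""Core in-memory containers shared across the pipeline.

All signals are stored in microvolts (µV).  Continuous recordings are
``channel x sample`` matrices; epoched data are ``trial x channel x sample``
arrays with one class label per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The eight scalp electrodes used throughout (10-20 system).
CHANNELS: tuple[str, ...] = ("FP2", "F8", "C3", "Cz", "C4", "O1", "Oz", "O2")

#: The two visual-imagery classes: a static picture vs a picture moving right.
CLASSES: tuple[str, str] = ("static", "moving")


@dataclass
class EEGRecording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per row of ``data``.
    t0 : float
        Time of the first sample in seconds relative to trial onset.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channel x sample)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        """Return one channel by name (case-insensitive)."""
        labels = [c.lower() for c in self.channel_labels]
        try:
            return self.data[labels.index(label.lower())]
        except ValueError:
            raise KeyError(f"channel {label!r} not in {self.channel_labels}") from None


@dataclass
class TrialSet:
    """Epoched trials with class labels.

    ``trials`` has shape (n_trials, n_channels, n_samples); ``window`` is the
    epoch extent in seconds relative to imagery onset.
    """

    trials: np.ndarray
    labels: np.ndarray
    fs: float
    channel_labels: list[str]
    window: tuple[float, float] = (0.0, 4.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.trials.ndim != 3:
            raise ValueError("trials must be 3-D (trial x channel x sample)")
        if len(self.labels) != self.trials.shape[0]:
            raise ValueError("one label per trial required")
        bad = set(self.labels.tolist()) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        n_expected = round((self.window[1] - self.window[0]) * self.fs)
        if self.trials.shape[0] and n_expected != self.trials.shape[2]:
            raise ValueError(
                f"window {self.window} at fs={self.fs} implies {n_expected} samples, "
                f"got {self.trials.shape[2]}"
            )

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    def channel_index(self, label: str) -> int:
        labels = [c.lower() for c in self.channel_labels]
        try:
            return labels.index(label.lower())
        except ValueError:
            raise KeyError(f"channel {label!r} not in {self.channel_labels}") from None


@dataclass
class FeatureMatrix:
    """Per-trial feature vectors with named columns and class labels."""

    X: np.ndarray
    names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (trial x feature)")
        if self.X.shape[1] != len(self.names):
            raise ValueError("one name per feature column required")
        if self.X.shape[0] != len(self.labels):
            raise ValueError("one label per trial required")
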