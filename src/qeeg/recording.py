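"""In-memory containers for continuous recordings and epoch sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EEGRecording:
    """A continuous multichannel EEG signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    fs : float
        Sampling frequency in Hz.
    channel_labels : list of str
        Ordered 10-20 channel names; must be unique.
    subject_id : str
        Identifier carried through the pipeline.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_labels.index(label)]

    def copy_with(self, samples: np.ndarray, channel_labels: list[str] | None = None) -> "EEGRecording":
        return EEGRecording(
            samples=samples,
            fs=self.fs,
            channel_labels=list(channel_labels if channel_labels is not None else self.channel_labels),
            subject_id=self.subject_id,
        )


@dataclass
class EpochSet:
    """Fixed-length artifact-free segments: the unit of quantitative analysis.

    ``epochs`` is a 3-D array (n_epochs, n_channels, n_times). All epochs
    share shape, sampling rate and channel order.
    """

    epochs: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = ""
    offsets: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (n_epochs, n_channels, n_times)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.epochs.shape[1]:
            raise ValueError("label count does not match channel axis")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[2]

    @property
    def epoch_length_s(self) -> float:
        return self.n_times / self.fs
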