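"""In-memory containers for continuous and epoched multichannel EEG."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RawRecording:
    """Continuous multichannel signal in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs_hz : float
        Sampling rate.
    channel_labels : list of str
        10-20 electrode names, unique.
    subject_id : str
    """

    data: np.ndarray
    fs_hz: float
    channel_labels: list[str]
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaN")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def copy_with(self, data: np.ndarray, channel_labels: list[str] | None = None) -> "RawRecording":
        return RawRecording(
            data=np.asarray(data, dtype=float),
            fs_hz=self.fs_hz,
            channel_labels=list(self.channel_labels if channel_labels is None else channel_labels),
            subject_id=self.subject_id,
        )


@dataclass
class EpochedRecording:
    """Signal segmented into fixed-length epochs.

    data has shape (n_epochs, n_channels, n_samples_per_epoch) with
    n_samples_per_epoch == epoch_len_s * fs_hz exactly.
    """

    data: np.ndarray
    fs_hz: float
    channel_labels: list[str]
    epoch_len_s: float = 5.0
    subject_id: str = "unknown"
    retained_epoch_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        if self.data.shape[0] < 1:
            raise ValueError("at least one epoch required")
        expected = int(round(self.epoch_len_s * self.fs_hz))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.data.shape[2]} samples != epoch_len_s*fs = {expected}"
            )
        if not self.retained_epoch_indices:
            self.retained_epoch_indices = list(range(self.data.shape[0]))

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]
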