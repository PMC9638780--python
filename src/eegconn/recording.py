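"""Multi-channel EEG recording container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Recording:
    """Voltage matrix in microvolts plus sampling metadata.

    ``data`` has shape (n_channels, n_samples).  ``accel`` is an optional
    single accelerometer magnitude trace sampled at the same rate (arbitrary
    units; the scorer only uses its variance).
    """

    data: np.ndarray
    fs: float
    channel_ids: np.ndarray | None = None
    accel: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.data.shape[0])
        else:
            self.channel_ids = np.asarray(self.channel_ids)
            if len(self.channel_ids) != self.data.shape[0]:
                raise ValueError("channel_ids length mismatch")
        if self.accel is not None:
            self.accel = np.asarray(self.accel, dtype=float)
            if self.accel.shape[-1] != self.data.shape[1]:
                raise ValueError("accelerometer length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, channel_id: int) -> np.ndarray:
        idx = np.flatnonzero(self.channel_ids == channel_id)
        if idx.size == 0:
            raise KeyError(f"channel id {channel_id} not in recording")
        return self.data[idx[0]]
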