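"""Lightweight epoched multichannel time-series container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass
class EpochArray:
    """Epoched data: trials × channels × samples with a uniform time axis.

    ``trial_index`` keys each epoch back into the session's trial table.
    Time 0 is stimulus onset.
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    channels: list[str] = field(default_factory=list)
    trial_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[2] != self.times.size:
            raise ValueError("times length does not match data")
        dt = np.diff(self.times)
        if dt.size and (np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.fs, rtol=1e-6)):
            raise ValueError("times must be strictly increasing at 1/fs")
        if not (self.times[0] <= 0.0 <= self.times[-1]):
            raise ValueError("stimulus onset (0 s) must lie inside the epoch")
        if not self.channels:
            self.channels = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        if self.trial_index is None:
            self.trial_index = np.arange(self.data.shape[0])
        else:
            self.trial_index = np.asarray(self.trial_index, dtype=int)
            if np.unique(self.trial_index).size != self.trial_index.size:
                raise ValueError("trial keys must be unique")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def select(self, mask: np.ndarray) -> "EpochArray":
        """Subset trials by boolean mask or index array."""
        return EpochArray(self.data[mask], self.times, self.fs,
                          list(self.channels), self.trial_index[mask])

    def save(self, path: str) -> None:
        np.savez(path, data=self.data, times=self.times, fs=self.fs,
                 channels=np.array(self.channels), trial_index=self.trial_index)

    @classmethod
    def load(cls, path: str) -> "EpochArray":
        with np.load(path, allow_pickle=False) as f:
            return cls(f["data"], f["times"], float(f["fs"]),
                       [str(c) for c in f["channels"]], f["trial_index"])


def epoch_times(tmin: float, tmax: float, fs: float) -> np.ndarray:
    """Sample grid on multiples of 1/fs covering [tmin, tmax]."""
    k0 = int(np.ceil(tmin * fs - 1e-9))
    k1 = int(np.floor(tmax * fs + 1e-9))
    return np.arange(k0, k1 + 1) / fs


def bandpass(data: np.ndarray, fs: float, lo: float = 2.0, hi: float = 40.0,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last (time) axis."""
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)
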