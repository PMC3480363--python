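"""Core EEG container shared by the whole pipeline.

A recording is a pair of frontal-pole voltage series (Fp1, Fp2) in microvolts
at a fixed sampling rate.  Time is 0-based seconds from the start of the
recording; sample ``i`` is taken at ``start_time + i / fs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_CHANNELS = ("Fp1", "Fp2")


@dataclass
class EEGRecording:
    """Two-channel EEG voltage series.

    Parameters
    ----------
    fs : float
        Sampling rate in Hz.
    data : ndarray, shape (2, n_samples)
        Per-channel voltages in microvolts, rows ordered like ``channels``.
    channels : tuple of str
        Channel labels, ``("Fp1", "Fp2")`` by default.
    start_time : float
        Offset of the first sample in seconds (0-based convention).
    """

    fs: float
    data: np.ndarray
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data must have shape (n_channels={len(self.channels)}, n_samples), "
                f"got {self.data.shape}"
            )
        if self.data.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Span of the recording in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds (0-based, relative to start_time)."""
        return self.start_time + np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {self.channels}") from None
        return self.data[idx]

    def slice(self, t0: float, t1: float) -> "EEGRecording":
        """Return the sub-recording covering [t0, t1) in recording-local time."""
        i0 = int(round((t0 - self.start_time) * self.fs))
        i1 = int(round((t1 - self.start_time) * self.fs))
        if not (0 <= i0 < i1 <= self.n_samples):
            raise ValueError(
                f"slice [{t0}, {t1}) outside recording span "
                f"[{self.start_time}, {self.start_time + self.duration})"
            )
        return EEGRecording(
            fs=self.fs,
            data=self.data[:, i0:i1].copy(),
            channels=self.channels,
            start_time=t0,
        )

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            fs=self.fs,
            data=self.data.copy(),
            channels=self.channels,
            start_time=self.start_time,
        )


@dataclass
class Block:
    """One fixed-length analysis block cut from a recording."""

    start: float  # block start time, seconds
    fs: float
    data: np.ndarray = field(repr=False)  # (2, n) µV

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs
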