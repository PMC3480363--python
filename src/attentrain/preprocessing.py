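"""Artifact screening and block segmentation.

Raw frontal EEG from dry-sensor headsets suffers two characteristic
hardware defects: saturated digital samples (the amplifier rails) and
disconnected electrodes (the trace goes flat).  Any abnormal reading,
together with everything within a guard window of two seconds around it,
is excluded from analysis; the surviving signal is tiled into consecutive
2-second blocks for spectral feature extraction.

Conventions: half-open time intervals [a, b) in 0-based seconds; block
tiling is anchored at the recording start and a trailing partial block is
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import Block, EEGRecording

SATURATION = "saturation"
DISCONNECTION = "disconnection"

DEFAULT_RAIL_UV = 512.0
DEFAULT_FLAT_EPS_UV = 0.1
DEFAULT_FLAT_WINDOW_S = 1.0
DEFAULT_GUARD_S = 2.0
DEFAULT_BLOCK_LEN_S = 2.0


def _merge(intervals: list[tuple[float, float, str]]) -> tuple[list[tuple[float, float]], list[str]]:
    """Sort and merge overlapping/touching intervals, combining reason tags."""
    if not intervals:
        return [], []
    intervals = sorted(intervals)
    merged: list[tuple[float, float]] = []
    reasons: list[set[str]] = []
    for a, b, r in intervals:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            reasons[-1].add(r)
        else:
            merged.append((a, b))
            reasons.append({r})
    return merged, ["+".join(sorted(rs)) for rs in reasons]


@dataclass
class ArtifactMask:
    """Excluded time intervals with per-interval reason tags.

    Intervals are half-open [a, b) seconds, sorted, merged and
    non-overlapping; a reason is 'saturation', 'disconnection', or a
    '+'-joined combination when merged events mix causes.
    """

    excluded: list[tuple[float, float]] = field(default_factory=list)
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.excluded) != len(self.reasons):
            raise ValueError("excluded and reasons must have equal length")
        merged, reasons = _merge(
            [(a, b, r) for (a, b), r in zip(self.excluded, self.reasons)])
        self.excluded = merged
        self.reasons = reasons

    @property
    def total_excluded(self) -> float:
        return float(sum(b - a for a, b in self.excluded))

    def overlaps(self, a: float, b: float) -> bool:
        """Does [a, b) intersect any excluded interval (positive measure)?"""
        return any(a < e and s < b for s, e in self.excluded)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start_s": [a for a, _ in self.excluded],
             "end_s": [b for _, b in self.excluded],
             "reason": self.reasons})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ArtifactMask":
        return cls(excluded=list(zip(df["start_s"], df["end_s"])),
                   reasons=list(df["reason"]))


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs [i0, i1) where flags is True."""
    if not flags.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], flags, [False]))))
    return list(zip(edges[::2], edges[1::2]))


def detect_artifacts(rec: EEGRecording,
                     rail: float = DEFAULT_RAIL_UV,
                     flat_eps: float = DEFAULT_FLAT_EPS_UV,
                     flat_window: float = DEFAULT_FLAT_WINDOW_S,
                     guard: float = DEFAULT_GUARD_S) -> ArtifactMask:
    """Screen a recording for saturation and disconnection events.

    A sample with |x| >= ``rail`` on either channel is a saturation event;
    a window of ``flat_window`` seconds whose per-channel standard
    deviation falls below ``flat_eps`` on either channel is a
    disconnection event.  Every event is expanded by ``guard`` seconds on
    both sides (the conservative reading of "within two seconds of the
    abnormality") and overlapping exclusions are merged.
    """
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    if rail <= 0 or flat_window <= 0 or guard < 0:
        raise ValueError("need rail > 0, flat_window > 0, guard >= 0")
    fs = rec.fs
    t0 = rec.start_time
    span_end = t0 + rec.duration
    raw: list[tuple[float, float, str]] = []

    sat = (np.abs(rec.data) >= rail).any(axis=0)
    for i0, i1 in _runs(sat):
        # events are the sample times i/fs for i in [i0, i1); each expands
        # to [t - guard, t + guard), so the run covers the union below
        raw.append((t0 + i0 / fs - guard, t0 + (i1 - 1) / fs + guard, SATURATION))

    w = int(round(flat_window * fs))
    if rec.n_samples >= w:
        flat_any = np.zeros(rec.n_samples - w + 1, dtype=bool)
        for ch in rec.data:
            x = ch - ch.mean()  # centring keeps the cumsum variance stable
            c1 = np.concatenate(([0.0], np.cumsum(x)))
            c2 = np.concatenate(([0.0], np.cumsum(x * x)))
            s1 = c1[w:] - c1[:-w]
            s2 = c2[w:] - c2[:-w]
            var = np.maximum(s2 / w - (s1 / w) ** 2, 0.0)
            flat_any |= np.sqrt(var) < flat_eps
        for i0, i1 in _runs(flat_any):
            # flagged window starts span [i0, i1); the defect covers up to
            # the end of the last flagged window
            a = t0 + i0 / fs
            b = t0 + (i1 - 1 + w) / fs
            raw.append((a - guard, b + guard, DISCONNECTION))

    clipped = [(max(a, t0), min(b, span_end), r) for a, b, r in raw
               if min(b, span_end) > max(a, t0)]
    excluded, reasons = _merge(clipped)
    return ArtifactMask(excluded=excluded, reasons=reasons)


def apply_mask(rec: EEGRecording, mask: ArtifactMask,
               block_len: float = DEFAULT_BLOCK_LEN_S) -> list[Block]:
    """Tile the recording into blocks and drop any touching the mask.

    The recording is cut into consecutive non-overlapping ``block_len``
    blocks anchored at its start; a block overlapping any excluded
    interval is dropped, as is a trailing partial block.  May return an
    empty list when the mask covers everything — callers must handle it.
    """
    if block_len <= 0:
        raise ValueError("block_len must be positive")
    nb = int(round(block_len * rec.fs))
    if nb < 1:
        raise ValueError("block_len shorter than one sample")
    blocks: list[Block] = []
    n_blocks = rec.n_samples // nb
    for k in range(n_blocks):
        a = rec.start_time + k * nb / rec.fs
        b = rec.start_time + (k + 1) * nb / rec.fs
        if mask.overlaps(a, b):
            continue
        blocks.append(Block(start=a, fs=rec.fs,
                            data=rec.data[:, k * nb:(k + 1) * nb]))
    return blocks
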