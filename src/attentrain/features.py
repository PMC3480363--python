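"""Filter-bank band-power features from two frontal channels plus a
virtual differential channel.

Each clean 2-second block is transformed with a 256-point FFT; power in
each of 8 contiguous bands covering 4–30 Hz is summed over the discrete
frequencies inside the band, and band powers are averaged over blocks.
This is done per channel (Fp1, Fp2) and for the virtual channel
Fp1 − Fp2, a fixed bipolar derivation that cancels common-mode ocular
artifacts, giving a 24-element feature vector per recording or epoch.

The one-sided power spectrum is normalised so that its total equals the
block mean square (Parseval); feature ordering is channel-major,
band-minor: Fp1 bands 0–7, Fp2 bands 0–7, diff bands 0–7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .recording import Block

FFT_LENGTH = 256
CHANNEL_ORDER = ("Fp1", "Fp2", "diff")
LOG_EPS = 1e-12


@dataclass(frozen=True)
class FilterBank:
    """Ordered contiguous half-open frequency bands [low, high) in Hz."""

    bands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("filter bank needs at least one band")
        for (lo, hi) in self.bands:
            if hi <= lo:
                raise ValueError(f"band ({lo}, {hi}) has non-positive width")
        for (_, prev_hi), (lo, _) in zip(self.bands, self.bands[1:]):
            if abs(prev_hi - lo) > 1e-9:
                raise ValueError("bands must be contiguous and non-overlapping")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def span(self) -> tuple[float, float]:
        return (self.bands[0][0], self.bands[-1][1])


def default_bank() -> FilterBank:
    """8 equal-width bands (3.25 Hz each) covering 4–30 Hz contiguously."""
    edges = np.linspace(4.0, 30.0, 9)
    return FilterBank(tuple((float(a), float(b))
                            for a, b in zip(edges[:-1], edges[1:])))


def classical_bank() -> FilterBank:
    """8 bands at traditional rhythm boundaries (theta, alpha, beta splits)."""
    edges = [4.0, 8.0, 10.0, 12.0, 15.0, 18.0, 22.0, 26.0, 30.0]
    return FilterBank(tuple((float(a), float(b))
                            for a, b in zip(edges[:-1], edges[1:])))


@dataclass
class FeatureVector:
    """Band-power features: (channel in Fp1, Fp2, diff) x (band 0..n-1)."""

    values: np.ndarray
    n_blocks: int
    log_scale: bool
    bank: FilterBank = field(default_factory=default_bank)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = len(CHANNEL_ORDER) * self.bank.n_bands
        if self.values.shape != (expected,):
            raise ValueError(
                f"expected {expected} features "
                f"({len(CHANNEL_ORDER)} channels x {self.bank.n_bands} bands), "
                f"got shape {self.values.shape}")
        if not self.log_scale and (self.values < 0).any():
            raise ValueError("raw band powers must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def feature_names(self) -> list[str]:
        return [f"{ch}_band{j}" for ch in CHANNEL_ORDER
                for j in range(self.bank.n_bands)]

    def to_frame(self) -> pd.DataFrame:
        row = dict(zip(self.feature_names, self.values))
        row["n_blocks"] = self.n_blocks
        return pd.DataFrame([row])


def virtual_channel(fp1: np.ndarray, fp2: np.ndarray) -> np.ndarray:
    """Differential potential Fp1 − Fp2 (elementwise)."""
    fp1 = np.asarray(fp1, dtype=float)
    fp2 = np.asarray(fp2, dtype=float)
    if fp1.shape != fp2.shape:
        raise ValueError(
            f"channel length mismatch: {fp1.shape} vs {fp2.shape}")
    return fp1 - fp2


def block_spectrum(block: np.ndarray, fs: float,
                   window: str = "rectangular") -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of one 256-sample block.

    Power at bin k is |X_k|^2 / N^2 with the usual doubling for
    0 < k < N/2, so the one-sided total equals the block mean square.

    Returns
    -------
    freqs : ndarray, shape (N/2 + 1,)
        Bin frequencies k * fs / N.
    power : ndarray, same shape
        One-sided power per bin (signal units squared).
    """
    x = np.asarray(block, dtype=float)
    if x.shape != (FFT_LENGTH,):
        raise ValueError(
            f"block must contain exactly {FFT_LENGTH} samples, got {x.shape}")
    if window == "hann":
        x = x * np.hanning(FFT_LENGTH)
    elif window != "rectangular":
        raise ValueError(f"unknown window {window!r}")
    spectrum = np.fft.rfft(x)
    power = np.abs(spectrum) ** 2 / FFT_LENGTH**2
    power[1:-1] *= 2.0  # one-sided doubling, DC and Nyquist excluded
    freqs = np.fft.rfftfreq(FFT_LENGTH, d=1.0 / fs)
    return freqs, power


def band_power(power: np.ndarray, freqs: np.ndarray,
               band: tuple[float, float]) -> float:
    """Sum of one-sided spectral power over bins with low <= f < high."""
    lo, hi = band
    # nudge the edge comparison so bins that land exactly on an edge
    # (up to float rounding) go to the band whose low edge they equal
    tol = 1e-9
    mask = (freqs >= lo - tol) & (freqs < hi - tol)
    if not mask.any():
        raise ValueError(
            f"band ({lo}, {hi}) Hz contains no FFT bins at this resolution")
    return float(power[mask].sum())


def _resample_to_fft_length(x: np.ndarray) -> np.ndarray:
    """Linear resampling of a block to the fixed FFT length."""
    n = len(x)
    if n == FFT_LENGTH:
        return x
    old = np.linspace(0.0, 1.0, n)
    new = np.linspace(0.0, 1.0, FFT_LENGTH)
    return np.interp(new, old, x)


def extract_features(blocks: Sequence[Block],
                     bank: FilterBank | None = None,
                     log_scale: bool = True,
                     window: str = "rectangular") -> FeatureVector:
    """Average band powers over clean blocks into one feature vector.

    For every block and each of the three derivations (Fp1, Fp2,
    Fp1 − Fp2) the band powers of ``bank`` are computed and averaged
    across blocks; with ``log_scale`` the averaged powers are mapped
    through log10(x + 1e-12) for variance stabilisation.

    Raises
    ------
    ValueError
        If ``blocks`` is empty (a fully masked recording upstream).
    """
    if bank is None:
        bank = default_bank()
    blocks = list(blocks)
    if not blocks:
        raise ValueError(
            "no clean blocks to extract features from (recording fully "
            "masked by artifact screening?)")
    acc = np.zeros(len(CHANNEL_ORDER) * bank.n_bands)
    for blk in blocks:
        fp1, fp2 = blk.data[0], blk.data[1]
        series = (fp1, fp2, virtual_channel(fp1, fp2))
        # fs != 128 Hz blocks are linearly resampled so the FFT length
        # stays fixed; the bin frequencies then follow the true fs
        for c, x in enumerate(series):
            xr = _resample_to_fft_length(np.asarray(x, dtype=float))
            freqs, power = block_spectrum(xr, blk.fs * FFT_LENGTH / len(x),
                                          window=window)
            for j, band in enumerate(bank.bands):
                acc[c * bank.n_bands + j] += band_power(power, freqs, band)
    values = acc / len(blocks)
    if log_scale:
        values = np.log10(values + LOG_EPS)
    return FeatureVector(values=values, n_blocks=len(blocks),
                         log_scale=log_scale, bank=bank)


def features_to_frame(fvs: Iterable[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into one table (one row per recording/epoch)."""
    return pd.concat([fv.to_frame() for fv in fvs], ignore_index=True)
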