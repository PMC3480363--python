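"""Reading and writing the pipeline's file formats.

* Recordings: CSV (columns ``time_s, fp1_uV, fp2_uV``) and EDF (European
  Data Format; two signals "Fp1"/"Fp2" in µV).  EDF files are written by a
  small built-in writer (the format is fixed-width ASCII headers plus
  little-endian int16 samples) and read through :mod:`mne` when available.
* Calibration epoch labels: CSV ``epoch_start_s, epoch_end_s, label``.
* Trial tables: ratings CSV ``subject_id, week, IA, HI, COM`` (blank =
  missing) and BASM CSV ``subject_id, week, basm``.
"""

from __future__ import annotations

import datetime as dt
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import DEFAULT_CHANNELS, EEGRecording

# ---------------------------------------------------------------- CSV --


def write_recording_csv(rec: EEGRecording, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": rec.times,
                       "fp1_uV": rec.channel("Fp1"),
                       "fp2_uV": rec.channel("Fp2")})
    df.to_csv(path, index=False)


def read_recording_csv(path: str | Path) -> EEGRecording:
    df = pd.read_csv(path)
    for col in ("time_s", "fp1_uV", "fp2_uV"):
        if col not in df.columns:
            raise ValueError(f"recording CSV missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("recording CSV needs at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    data = np.vstack([df["fp1_uV"].to_numpy(dtype=float),
                      df["fp2_uV"].to_numpy(dtype=float)])
    return EEGRecording(fs=fs, data=data, channels=DEFAULT_CHANNELS,
                        start_time=float(t[0]))


def write_labels_csv(epochs: list[tuple[float, float, str]],
                     path: str | Path) -> None:
    pd.DataFrame(epochs, columns=["epoch_start_s", "epoch_end_s", "label"]
                 ).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> list[tuple[float, float, str]]:
    df = pd.read_csv(path)
    return [(float(a), float(b), str(l)) for a, b, l in
            zip(df["epoch_start_s"], df["epoch_end_s"], df["label"])]


def write_ratings_csv(ratings: pd.DataFrame, path: str | Path) -> None:
    ratings.to_csv(path, index=False)


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["week"] = df["week"].astype(int)
    return df


def write_basm_csv(basm: pd.DataFrame, path: str | Path) -> None:
    basm.to_csv(path, index=False)


def read_basm_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["week"] = df["week"].astype(int)
    return df


# ---------------------------------------------------------------- EDF --

_EDF_HEADER_FIXED = 256
_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a two-channel recording as EDF.

    Data records are one second long, so the sampling rate must be a
    positive integer; a trailing partial second is zero-padded.  Physical
    ranges are chosen per channel to cover the observed amplitudes, and
    samples are quantised to 16 bits (relative error ~3e-5 of the range).
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9 or fs < 1:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_sig = len(rec.channels)
    n_records = math.ceil(rec.n_samples / fs)
    padded = np.zeros((n_sig, n_records * fs))
    padded[:, :rec.n_samples] = rec.data

    phys_min, phys_max, scaled = [], [], []
    for ch in padded:
        amp = max(float(np.max(np.abs(ch))), 1.0)
        lo, hi = -amp, amp
        phys_min.append(lo)
        phys_max.append(hi)
        digital = np.round((ch - lo) / (hi - lo)
                           * (_DIG_MAX - _DIG_MIN) + _DIG_MIN)
        scaled.append(digital.astype("<i2"))

    now = dt.datetime(2000, 1, 1)
    header = b"".join([
        _ascii("0", 8),                       # version
        _ascii("X X X X", 80),                # patient id (anonymous)
        _ascii("Startdate X X X X", 80),      # recording id
        _ascii(now.strftime("%d.%m.%y"), 8),
        _ascii(now.strftime("%H.%M.%S"), 8),
        _ascii(_EDF_HEADER_FIXED * (n_sig + 1), 8),
        _ascii("", 44),                       # reserved
        _ascii(n_records, 8),
        _ascii("1", 8),                       # record duration, seconds
        _ascii(n_sig, 4),
    ])
    fields = [
        [ _ascii(label, 16) for label in rec.channels ],           # label
        [ _ascii("EEG dry electrode", 80) ] * n_sig,               # transducer
        [ _ascii("uV", 8) ] * n_sig,                               # unit
        [ _ascii(f"{m:.3f}", 8) for m in phys_min ],
        [ _ascii(f"{m:.3f}", 8) for m in phys_max ],
        [ _ascii(_DIG_MIN, 8) ] * n_sig,
        [ _ascii(_DIG_MAX, 8) ] * n_sig,
        [ _ascii("", 80) ] * n_sig,                                # prefilter
        [ _ascii(fs, 8) ] * n_sig,                                 # samples/record
        [ _ascii("", 32) ] * n_sig,                                # reserved
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        for r in range(n_records):
            for sig in scaled:
                fh.write(sig[r * fs:(r + 1) * fs].tobytes())


def read_recording_edf(path: str | Path) -> EEGRecording:
    """Read a two-channel EDF recording (requires :mod:`mne`)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    picks = [ch for ch in DEFAULT_CHANNELS if ch in raw.ch_names]
    if len(picks) != 2:
        raise ValueError(
            f"EDF must contain channels {DEFAULT_CHANNELS}, found {raw.ch_names}")
    data = raw.get_data(picks=picks) * 1e6  # mne loads EEG in volts
    return EEGRecording(fs=float(raw.info["sfreq"]), data=data,
                        channels=DEFAULT_CHANNELS)


def read_recording(path: str | Path) -> EEGRecording:
    """Dispatch on file extension (.csv or .edf)."""
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return read_recording_csv(path)
    if suffix == ".edf":
        return read_recording_edf(path)
    raise ValueError(f"unsupported recording format {suffix!r}")


def write_recording(rec: EEGRecording, path: str | Path) -> None:
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        write_recording_csv(rec, path)
    elif suffix == ".edf":
        write_recording_edf(rec, path)
    else:
        raise ValueError(f"unsupported recording format {suffix!r}")
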