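"""Synthetic EEG, calibration datasets, and trial tables.

The generator emulates the signals and tables the rest of the pipeline
assumes, so every stage is testable without hardware:

* state-dependent EEG spectra — an inattentive state with elevated theta
  (4–8 Hz) and reduced beta (13–30 Hz) power, an attentive state with the
  reverse, riding on 1/f (pink) background noise;
* ocular blink transients, common-mode on both frontal channels;
* hardware defects (saturated samples, flatlined/disconnected stretches);
* a single-arm trial table with baseline-severity-dependent improvement,
  dropout, and a negative coupling between the EEG-derived attention change
  and the behavioural-rating change.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
seeds and arguments give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .recording import DEFAULT_CHANNELS, EEGRecording

#: (low, high) Hz of the oscillation bands realised by StateProfile.
THETA_BAND = (4.0, 8.0)
ALPHA_BAND = (8.0, 12.0)
BETA_BAND = (13.0, 30.0)

BLINK_DURATION_S = 0.3  # half-sine blink transient width

TRIAL_WEEKS = (0, 4, 8, 20, 24)
SUBSCALE_MAX = {"IA": 27, "HI": 27, "COM": 54}


@dataclass(frozen=True)
class StateProfile:
    """Spectral recipe for one attentional state.

    Amplitudes are RMS microvolts of the band-limited component over the
    whole recording; ``blink_rate`` is events per minute and ``blink_amp``
    the peak microvolts of the 300 ms half-sine blink transient.
    """

    theta_amp: float
    alpha_amp: float
    beta_amp: float
    pink_noise_amp: float
    blink_rate: float = 0.0
    blink_amp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("theta_amp", "alpha_amp", "beta_amp", "pink_noise_amp",
                     "blink_rate", "blink_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def theta_beta_ratio(self) -> float:
        if self.beta_amp == 0:
            return float("inf") if self.theta_amp > 0 else float("nan")
        return self.theta_amp / self.beta_amp


# Default study conditions: attentive theta/beta amplitude ratio 0.5,
# inattentive 4 — the contrast reported for ADHD resting EEG (elevated
# slow-wave, reduced fast-wave activity when inattentive).
ATTENTIVE_PROFILE = StateProfile(
    theta_amp=2.0, alpha_amp=6.0, beta_amp=4.0,
    pink_noise_amp=10.0, blink_rate=8.0, blink_amp=150.0,
)
INATTENTIVE_PROFILE = StateProfile(
    theta_amp=16.0, alpha_amp=6.0, beta_amp=4.0,
    pink_noise_amp=10.0, blink_rate=8.0, blink_amp=150.0,
)


@dataclass
class CalibrationDataset:
    """Labelled epochs from a calibration run (attention task vs rest)."""

    epochs: list[tuple[EEGRecording, str]]
    subject_id: str = "anon"

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for _, label in self.epochs:
            counts[label] = counts.get(label, 0) + 1
        if set(counts) != {"attentive", "relaxed"} or min(counts.values()) < 2:
            raise ValueError(
                "calibration dataset needs >= 2 epochs of each label "
                f"('attentive', 'relaxed'); got counts {counts}"
            )

    @property
    def labels(self) -> list[str]:
        return [label for _, label in self.epochs]


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        band: tuple[float, float], rms: float) -> np.ndarray:
    """Narrowband oscillation: band-pass filtered white noise scaled to rms."""
    if rms == 0.0:
        return np.zeros(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    current = np.sqrt(np.mean(x**2))
    if current == 0.0:
        return np.zeros(n)
    return x * (rms / current)


def _pink_noise(rng: np.random.Generator, n: int, rms: float) -> np.ndarray:
    """1/f spectral shaping of white noise; amplitude is broadband RMS."""
    if rms == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spectrum * scale, n)
    current = np.sqrt(np.mean(x**2))
    return x * (rms / current) if current > 0 else np.zeros(n)


def _blink_train(rng: np.random.Generator, n: int, fs: float,
                 rate_per_min: float, amp: float, duration_s: float) -> np.ndarray:
    """Half-sine blink transients at Poisson-distributed onsets."""
    out = np.zeros(n)
    if rate_per_min == 0.0 or amp == 0.0:
        return out
    width = max(int(round(BLINK_DURATION_S * fs)), 1)
    waveform = amp * np.sin(np.pi * np.arange(width) / width)
    n_events = rng.poisson(rate_per_min * duration_s / 60.0)
    if n_events == 0:
        return out
    onsets = rng.integers(0, max(n - width, 1), size=n_events)
    for i in np.sort(onsets):
        out[i:i + width] += waveform[: n - i]
    return out


def simulate_eeg(profile: StateProfile, duration: float, fs: float = 128.0,
                 seed: int = 0) -> EEGRecording:
    """Generate a two-channel frontal recording for one attentional state.

    Oscillations and background noise are drawn independently per channel;
    blink transients are identical on both channels (frontal ocular
    artifacts are common-mode, which is what the Fp1−Fp2 virtual channel
    exploits).

    Parameters
    ----------
    profile : StateProfile
        Spectral recipe (RMS amplitudes, blink statistics).
    duration : float
        Recording length in seconds; must be positive.
    fs : float
        Sampling rate in Hz; must exceed twice the 30 Hz band top.
    seed : int
        Seed for the generator; same seed and arguments reproduce the
        recording bit for bit.
    """
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    if fs <= 60.0:
        raise ValueError(
            f"fs={fs} Hz is below the Nyquist requirement for the 30 Hz band "
            "(need fs > 60 Hz)"
        )
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))

    blinks = _blink_train(rng, n, fs, profile.blink_rate, profile.blink_amp,
                          duration)
    data = np.empty((2, n))
    for ch in range(2):
        x = np.zeros(n)
        x += _band_limited_noise(rng, n, fs, THETA_BAND, profile.theta_amp)
        x += _band_limited_noise(rng, n, fs, ALPHA_BAND, profile.alpha_amp)
        x += _band_limited_noise(rng, n, fs, BETA_BAND, profile.beta_amp)
        x += _pink_noise(rng, n, profile.pink_noise_amp)
        data[ch] = x + blinks
    return EEGRecording(fs=fs, data=data, channels=DEFAULT_CHANNELS)


def inject_artifacts(rec: EEGRecording,
                     saturation_times: Sequence[float] = (),
                     flatline_intervals: Sequence[tuple[float, float]] = (),
                     rail_value: float = 512.0) -> EEGRecording:
    """Inject the two defect classes the artifact screener must find.

    Samples at ``saturation_times`` are clamped to ±``rail_value`` (sign of
    the existing sample, + for zero); each ``flatline_interval`` [a, b) is
    replaced, per channel, by the constant value at its first sample —
    emulating a disconnected electrode. All other samples are unchanged.
    """
    out = rec.copy()
    n = out.n_samples
    span = (rec.start_time, rec.start_time + rec.duration)
    for t in saturation_times:
        i = int(round((t - rec.start_time) * rec.fs))
        if not 0 <= i < n:
            raise ValueError(f"saturation time {t} s outside recording span {span}")
        signs = np.where(out.data[:, i] < 0, -1.0, 1.0)
        out.data[:, i] = signs * rail_value
    for (a, b) in flatline_intervals:
        i0 = int(round((a - rec.start_time) * rec.fs))
        i1 = int(round((b - rec.start_time) * rec.fs))
        if not (0 <= i0 < i1 <= n):
            raise ValueError(
                f"flatline interval [{a}, {b}) s outside recording span {span}"
            )
        out.data[:, i0:i1] = out.data[:, i0:i0 + 1]
    return out


def simulate_calibration(attentive: StateProfile = ATTENTIVE_PROFILE,
                         inattentive: StateProfile = INATTENTIVE_PROFILE,
                         n_epochs_per_label: int = 20,
                         epoch_len: float = 10.0,
                         fs: float = 128.0,
                         seed: int = 0,
                         block_len: float = 2.0,
                         subject_id: str = "anon") -> CalibrationDataset:
    """Generate a balanced labelled calibration dataset.

    'attentive' epochs are drawn from the attentive profile (correct
    attention-task attempts); 'relaxed' epochs from the inattentive profile
    (resting). Epoch length must be an integer multiple of the analysis
    block length so downstream block tiling is exact.
    """
    if n_epochs_per_label < 2:
        raise ValueError("need at least 2 epochs per label")
    n_blocks = epoch_len / block_len
    if abs(n_blocks - round(n_blocks)) > 1e-9 or round(n_blocks) < 1:
        raise ValueError(
            f"epoch_len={epoch_len} s is not a positive integer multiple of the "
            f"block length {block_len} s"
        )
    rng = np.random.default_rng(seed)
    epochs: list[tuple[EEGRecording, str]] = []
    for _ in range(n_epochs_per_label):
        for profile, label in ((attentive, "attentive"), (inattentive, "relaxed")):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            epochs.append((simulate_eeg(profile, epoch_len, fs, sub_seed), label))
    return CalibrationDataset(epochs=epochs, subject_id=subject_id)


@dataclass
class TrialSimConfig:
    """Parameters of the synthetic single-arm trial.

    Defaults reflect the modelled study: 20 children, parent-rated
    inattentive (IA) and hyperactive-impulsive (HI) baselines around
    17.7 (5.0) and 15.6 (3.9) points, improvement proportional to baseline
    severity (slope −0.7 change-points per baseline point), dropout
    hazards of 1/20 before week 4 and 2/19 between weeks 4 and 8, and a
    negative correlation (−0.6) between the week-0→20 change in the
    EEG-derived attention score (BASM) and the behavioural change.
    """

    n_subjects: int = 20
    baseline_mean: Mapping[str, float] = field(
        default_factory=lambda: {"IA": 17.7, "HI": 15.6})
    baseline_sd: Mapping[str, float] = field(
        default_factory=lambda: {"IA": 5.0, "HI": 3.9})
    effect_slope: float = -0.7
    # Intercept of the change model per subscale: change = intercept +
    # effect_slope * baseline + noise.  Defaults place the mean week-8
    # change at the observed -4.6 (IA) and -4.7 (HI) points given the
    # default baselines and slope.
    change_intercept: Mapping[str, float] = field(
        default_factory=lambda: {"IA": 0.7 * 17.7 - 4.6, "HI": 0.7 * 15.6 - 4.7})
    residual_sd: float = 3.0
    dropout_times: Mapping[int, float] = field(
        default_factory=lambda: {4: 1 / 20, 8: 2 / 19})
    basm_coupling: float = -0.6
    basm_baseline_mean: float = 60.9
    basm_baseline_sd: float = 81.0
    basm_change_mean: float = 32.5
    basm_change_sd: float = 60.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for sub, sd in self.baseline_sd.items():
            if sd <= 0:
                raise ValueError(f"baseline_sd[{sub!r}] must be positive")
        for week, p in self.dropout_times.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"dropout probability at week {week} not in [0,1]")
        if not -1.0 <= self.basm_coupling <= 1.0:
            raise ValueError("basm_coupling must be a correlation in [-1, 1]")


def _truncnorm_scores(rng: np.random.Generator, mean: float, sd: float,
                      upper: float, size: int) -> np.ndarray:
    a, b = (0.0 - mean) / sd, (upper - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    return dist.rvs(size=size, random_state=rng)


def simulate_trial(cfg: TrialSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a (ratings, basm) table pair with the study's structure.

    Returns
    -------
    ratings : DataFrame with columns subject_id, week, IA, HI, COM.
        Integer subscores at weeks 0, 4, 8, 20, 24, clamped to the legal
        ranges, with COM = IA + HI; visits after a subject's dropout week
        are absent.
    basm : DataFrame with columns subject_id, week, basm.
        Raw attention scores at the week-0 and week-20 calibrations for
        subjects still enrolled, with the week-0→20 change negatively
        coupled (``basm_coupling``) to the combined-symptom change.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_subjects
    subjects = [f"S{i + 1:03d}" for i in range(n)]

    base = {
        sub: _truncnorm_scores(rng, cfg.baseline_mean[sub], cfg.baseline_sd[sub],
                               SUBSCALE_MAX[sub], n).round()
        for sub in ("IA", "HI")
    }
    # Follow-up model: score_w = baseline + f_w * (intercept + slope *
    # baseline) + noise, with the full effect (f_w = 1) at weeks >= 8 and
    # half of it at the interim week-4 visit; independent residuals per
    # visit, clamped to the legal scale range.
    scores: dict[str, dict[int, np.ndarray]] = {}
    for sub in ("IA", "HI"):
        scores[sub] = {0: base[sub].copy()}
        intercept = cfg.change_intercept.get(sub, 0.0)
        for week in TRIAL_WEEKS[1:]:
            frac = 0.5 if week == 4 else 1.0
            noise = rng.normal(0.0, cfg.residual_sd, size=n)
            raw = base[sub] + frac * (intercept + cfg.effect_slope * base[sub]) + noise
            scores[sub][week] = np.clip(raw.round(), 0, SUBSCALE_MAX[sub])

    # Dropout: a subject lost at week w contributes no visit at week >= w.
    dropout_week = np.full(n, np.inf)
    for week in sorted(cfg.dropout_times):
        p = cfg.dropout_times[week]
        at_risk = dropout_week == np.inf
        lost = at_risk & (rng.random(n) < p)
        dropout_week[lost] = week

    rows = []
    for i, sid in enumerate(subjects):
        for week in TRIAL_WEEKS:
            if week >= dropout_week[i]:
                continue
            ia = int(scores["IA"][week][i])
            hi = int(scores["HI"][week][i])
            rows.append({"subject_id": sid, "week": week,
                         "IA": ia, "HI": hi, "COM": ia + hi})
    ratings = pd.DataFrame(rows, columns=["subject_id", "week", "IA", "HI", "COM"])

    # BASM at the week-0 and week-20 calibrations. The change is built to
    # correlate (basm_coupling, typically negative) with the combined-
    # symptom change over the same span.
    delta_com = (scores["IA"][20] + scores["HI"][20]
                 - scores["IA"][0] - scores["HI"][0]).astype(float)
    z = (delta_com - delta_com.mean()) / (delta_com.std() or 1.0)
    c = cfg.basm_coupling
    eps = rng.standard_normal(n)
    delta_basm = cfg.basm_change_mean + cfg.basm_change_sd * (
        c * z + np.sqrt(max(1.0 - c**2, 0.0)) * eps)
    basm0 = rng.normal(cfg.basm_baseline_mean, cfg.basm_baseline_sd, size=n)

    basm_rows = []
    for i, sid in enumerate(subjects):
        basm_rows.append({"subject_id": sid, "week": 0, "basm": basm0[i]})
        if dropout_week[i] > 20:
            basm_rows.append({"subject_id": sid, "week": 20,
                              "basm": basm0[i] + delta_basm[i]})
    basm = pd.DataFrame(basm_rows, columns=["subject_id", "week", "basm"])
    return ratings, basm
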