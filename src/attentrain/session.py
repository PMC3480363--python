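"""Closed-loop training session and program schedule simulation.

During a session the EEG stream is cut into 2-second blocks, screened for
artifacts, scored by the calibrated attention model, and the smoothed
0–100 display score drives the game avatar at a proportional speed.
Blocks removed by artifact screening contribute no movement (the avatar
stands still), as do breaks.  The treatment program is an intensive phase
of 3 sessions per week for 8 weeks followed by 3 once-monthly booster
sessions.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import AttentionModel, basm_score
from .preprocessing import apply_mask, detect_artifacts
from .recording import EEGRecording
from .features import extract_features

INTENSIVE_SESSIONS_PER_WEEK = 3
INTENSIVE_WEEKS = 8
MAINTENANCE_SESSIONS = 3
DEFAULT_SESSION_S = 1800.0  # 30 minutes including breaks


@dataclass
class SessionTrace:
    """Per-block record of one training session."""

    times: np.ndarray          # block-end timestamps, s
    display_scores: np.ndarray  # smoothed display score per retained block
    speeds: np.ndarray         # avatar speed per block, units/s
    distance: float            # final cumulative track progress, units
    level: int = 1
    fruits_collected: int = 0
    block_len_s: float = 2.0

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.display_scores) == len(self.speeds)):
            raise ValueError("times, display_scores, speeds must align")
        if (np.asarray(self.speeds) < 0).any():
            raise ValueError("speeds must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times,
                             "score": self.display_scores,
                             "speed": self.speeds,
                             "distance": self.cumulative_distance})

    @property
    def cumulative_distance(self) -> np.ndarray:
        """Track progress after each retained block (uniform block length)."""
        if len(self.times) == 0:
            return np.array([])
        increments = np.asarray(self.speeds) * self.block_len_s
        return np.cumsum(increments)


def avatar_speed(score: float, v_max: float) -> float:
    """Avatar speed proportional to the 0–100 attention display score."""
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"display score {score} outside [0, 100]")
    if v_max <= 0:
        raise ValueError("v_max must be positive")
    return v_max * score / 100.0


def run_session(model: AttentionModel, eeg: EEGRecording,
                duration: float | None = None,
                v_max: float = 2.0,
                smoothing: int = 3,
                level: int = 1,
                seed: int = 0,
                screen: bool = True) -> SessionTrace:
    """Stream a recording through the scorer and integrate avatar motion.

    Consecutive clean blocks are scored, the display score is smoothed by
    a trailing moving average of ``smoothing`` blocks, and speed is
    integrated block by block into track distance.  Masked blocks
    contribute zero movement.  At levels 2–3 each retained block offers
    one floating fruit, collected with probability smoothed-score/100
    (Bernoulli, seeded) — the logbook count without the jump physics.
    """
    if duration is None:
        duration = min(eeg.duration, DEFAULT_SESSION_S)
    if duration <= 0:
        raise ValueError("duration must be positive")
    if smoothing < 1:
        raise ValueError("smoothing must be >= 1 block")
    if level not in (1, 2, 3):
        raise ValueError("level must be 1, 2 or 3")
    end = min(eeg.start_time + duration, eeg.start_time + eeg.duration)
    rec = eeg.slice(eeg.start_time, end)

    from .preprocessing import ArtifactMask
    mask = detect_artifacts(rec) if screen else ArtifactMask()
    blocks = apply_mask(rec, mask, block_len=model.block_len)

    rng = np.random.default_rng(seed)
    times, scores, speeds = [], [], []
    recent: list[float] = []
    distance = 0.0
    fruits = 0
    for blk in blocks:
        fv = extract_features([blk], bank=model.bank, log_scale=model.log_scale)
        s = basm_score(model, fv).display
        recent.append(s)
        if len(recent) > smoothing:
            recent.pop(0)
        smoothed = float(np.mean(recent))
        v = avatar_speed(smoothed, v_max)
        distance += v * blk.duration
        if level >= 2 and rng.random() < smoothed / 100.0:
            fruits += 1
        times.append(blk.start + blk.duration)
        scores.append(smoothed)
        speeds.append(v)
    return SessionTrace(times=np.array(times),
                        display_scores=np.array(scores),
                        speeds=np.array(speeds),
                        distance=distance, level=level,
                        fruits_collected=fruits,
                        block_len_s=model.block_len)


@dataclass
class ProgramSchedule:
    """Dated sessions of the full training program."""

    intensive: list[dt.date]
    maintenance: list[dt.date]

    def __post_init__(self) -> None:
        if len(self.intensive) != INTENSIVE_SESSIONS_PER_WEEK * INTENSIVE_WEEKS:
            raise ValueError(
                f"intensive phase must contain "
                f"{INTENSIVE_SESSIONS_PER_WEEK * INTENSIVE_WEEKS} sessions")
        if len(self.maintenance) != MAINTENANCE_SESSIONS:
            raise ValueError(
                f"maintenance phase must contain {MAINTENANCE_SESSIONS} sessions")
        all_dates = self.intensive + self.maintenance
        if any(b <= a for a, b in zip(all_dates, all_dates[1:])):
            raise ValueError("sessions must be strictly increasing in time")

    @property
    def sessions(self) -> list[tuple[str, dt.date]]:
        return ([("intensive", d) for d in self.intensive]
                + [("maintenance", d) for d in self.maintenance])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sessions, columns=["phase", "date"])


def build_schedule(start_date: dt.date) -> ProgramSchedule:
    """Build the 24-session intensive + 3 monthly booster schedule.

    Intensive sessions fall on days 0, 2 and 4 of each of the 8 weeks
    (e.g. Mon/Wed/Fri when started on a Monday); boosters follow at
    4-week intervals after the intensive phase.
    """
    if not isinstance(start_date, dt.date):
        raise TypeError("start_date must be a datetime.date")
    intensive = [start_date + dt.timedelta(days=7 * week + offset)
                 for week in range(INTENSIVE_WEEKS)
                 for offset in (0, 2, 4)]
    phase_end = start_date + dt.timedelta(days=7 * INTENSIVE_WEEKS)
    maintenance = [phase_end + dt.timedelta(days=28 * m)
                   for m in range(MAINTENANCE_SESSIONS)]
    return ProgramSchedule(intensive=intensive, maintenance=maintenance)
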