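"""Trial outcome statistics for the single-arm attention-training study.

Implements the outcome arithmetic of a parent-rated ADHD rating-scale
(ADHD-RS) study: 18-item scoring into inattentive (IA, 0–27),
hyperactive-impulsive (HI, 0–27) and combined (COM, 0–54) subscores;
last-observation-carried-forward (LOCF) imputation for the
intention-to-treat set; paired mean changes with t-tests;
baseline-predicts-change OLS regressions; Spearman correlations between
the change in the EEG-derived attention score (BASM) and the change in
rating-scale scores; and study-completion accounting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

SUBSCALES = ("IA", "HI", "COM")
DEFAULT_WEEKS = (0, 4, 8, 20, 24)
N_ITEMS = 18


def score_items(item_ratings: Sequence[int]) -> tuple[int, int, int]:
    """Score the 18 rating-scale items into (IA, HI, COM).

    Items 1–9 are the inattentive symptoms, items 10–18 the
    hyperactive-impulsive symptoms; each is rated 0–3 (never … very
    often).  IA and HI are the respective sums and COM their total.
    """
    items = list(item_ratings)
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} item ratings, got {len(items)}")
    if any(r not in (0, 1, 2, 3) for r in items):
        raise ValueError("each item rating must be in {0, 1, 2, 3}")
    ia = int(sum(items[:9]))
    hi = int(sum(items[9:]))
    return ia, hi, ia + hi


def locf(ratings: pd.DataFrame,
         drop_no_followup: bool = True,
         weeks: Sequence[int] = DEFAULT_WEEKS) -> pd.DataFrame:
    """Last-observation-carried-forward imputation of missing visits.

    Every subject's table is expanded to the full week grid and missing
    subscores are filled with the most recent earlier observation.
    Subjects without a baseline (week ``weeks[0]``) visit are dropped with
    a warning; with ``drop_no_followup`` subjects with no post-baseline
    data at all are also dropped (no follow-up to carry anything to —
    the intention-to-treat exclusion).
    Observed values are never altered.
    """
    weeks = sorted(weeks)
    out = []
    for sid, grp in ratings.groupby("subject_id", sort=True):
        grp = grp.set_index("week").reindex(weeks)
        baseline = grp.loc[weeks[0], SUBSCALES[0]] if weeks[0] in grp.index else np.nan
        if pd.isna(baseline):
            warnings.warn(f"subject {sid}: no baseline visit, dropped from LOCF")
            continue
        followup = grp.loc[grp.index > weeks[0], list(SUBSCALES)].notna().any(axis=None)
        if drop_no_followup and not followup:
            continue
        filled = grp[list(SUBSCALES)].ffill()
        filled["subject_id"] = sid
        filled["week"] = filled.index
        out.append(filled.reset_index(drop=True))
    if not out:
        return pd.DataFrame(columns=["subject_id", "week", *SUBSCALES])
    res = pd.concat(out, ignore_index=True)
    return res[["subject_id", "week", *SUBSCALES]]


@dataclass
class ChangeSummary:
    """Paired change of one subscale between two weeks."""

    subscale: str
    week_pair: tuple[int, int]
    n: int
    mean_change: float
    sd_change: float
    median_change: float
    range: tuple[float, float]
    t_statistic: float
    p_value: float
    degenerate: bool = False  # SD of differences was zero


def _paired(ratings: pd.DataFrame, subscale: str,
            week_a: int, week_b: int) -> pd.DataFrame:
    wide = ratings.pivot_table(index="subject_id", columns="week",
                               values=subscale, aggfunc="first")
    missing = [w for w in (week_a, week_b) if w not in wide.columns]
    if missing:
        raise ValueError(f"no observations at week(s) {missing}")
    pair = wide[[week_a, week_b]].dropna()
    return pair


def mean_change(ratings: pd.DataFrame, subscale: str,
                week_a: int = 0, week_b: int = 8) -> ChangeSummary:
    """Paired change week_b − week_a with a two-sided paired t-test.

    Subjects observed (or LOCF-filled) at both weeks contribute one
    paired difference.  A zero-SD difference vector cannot support a
    t-test; the summary is then flagged degenerate with p = 1 when the
    mean change is 0 (and p = 0 otherwise) instead of raising
    mid-pipeline.
    """
    if subscale not in SUBSCALES:
        raise ValueError(f"unknown subscale {subscale!r}")
    pair = _paired(ratings, subscale, week_a, week_b)
    if len(pair) < 2:
        raise ValueError("need >= 2 paired observations for a t-test")
    diff = (pair[week_b] - pair[week_a]).to_numpy(dtype=float)
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        mean = float(diff.mean())
        return ChangeSummary(subscale, (week_a, week_b), len(diff), mean, 0.0,
                             float(np.median(diff)),
                             (float(diff.min()), float(diff.max())),
                             t_statistic=float("nan"),
                             p_value=1.0 if mean == 0.0 else 0.0,
                             degenerate=True)
    t, p = sps.ttest_rel(pair[week_b], pair[week_a])
    return ChangeSummary(subscale, (week_a, week_b), len(diff),
                         float(diff.mean()), sd, float(np.median(diff)),
                         (float(diff.min()), float(diff.max())),
                         float(t), float(p))


def baseline_predicts_change(ratings: pd.DataFrame, subscale: str,
                             week_b: int = 8,
                             week_a: int = 0) -> tuple[float, float, float]:
    """OLS of the week_a→week_b change on the baseline score.

    Returns (slope, standard error, two-sided p).  A negative slope means
    more severe baselines improve more.
    """
    pair = _paired(ratings, subscale, week_a, week_b)
    if len(pair) < 3:
        raise ValueError("need >= 3 subjects with baseline and follow-up")
    baseline = pair[week_a].to_numpy(dtype=float)
    change = (pair[week_b] - pair[week_a]).to_numpy(dtype=float)
    if np.ptp(baseline) == 0:
        raise ValueError("baseline has zero variance; slope undefined")
    X = sm.add_constant(baseline)
    fit = sm.OLS(change, X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def basm_change_correlation(ratings: pd.DataFrame, basm: pd.DataFrame,
                            subscale: str,
                            week_pair: tuple[int, int] = (0, 20),
                            ) -> tuple[float, float]:
    """Spearman correlation of ΔBASM with Δsubscale over ``week_pair``.

    Ranks use average-tie handling; returns (rho, two-sided p).  Requires
    at least 4 subjects with both changes; constant change vectors are
    rejected (the correlation is undefined).
    """
    wa, wb = week_pair
    score_pair = _paired(ratings, subscale, wa, wb)
    basm_pair = _paired(basm, "basm", wa, wb) if "basm" in basm.columns else None
    if basm_pair is None:
        raise ValueError("basm table must have a 'basm' column")
    joined = pd.DataFrame({
        "d_score": score_pair[wb] - score_pair[wa],
        "d_basm": basm_pair[wb] - basm_pair[wa],
    }).dropna()
    if len(joined) < 4:
        raise ValueError("need >= 4 subjects with both changes")
    if np.ptp(joined["d_score"]) == 0 or np.ptp(joined["d_basm"]) == 0:
        raise ValueError("constant change vector; Spearman rho undefined")
    rho, p = sps.spearmanr(joined["d_basm"], joined["d_score"])
    return float(rho), float(p)


def completion_summary(disposition: Mapping[str, float | None],
                       ) -> tuple[int, int, float]:
    """Completion accounting from a subject → dropout-week mapping.

    ``None`` (or NaN) marks a completer.  Returns (n_enrolled,
    n_completed, percentage to one decimal).
    """
    n_enrolled = len(disposition)
    n_completed = sum(1 for w in disposition.values()
                      if w is None or (isinstance(w, float) and np.isnan(w)))
    pct = round(100.0 * n_completed / n_enrolled, 1) if n_enrolled else 0.0
    return n_enrolled, n_completed, pct


def visit_summary(ratings: pd.DataFrame,
                  weeks: Sequence[int] = DEFAULT_WEEKS) -> pd.DataFrame:
    """Per subscale × week sample size, mean and SD (a Table-1 layout)."""
    rows = []
    for week in weeks:
        sub = ratings[ratings["week"] == week]
        for subscale in SUBSCALES:
            vals = sub[subscale].dropna()
            rows.append({"week": week, "subscale": subscale,
                         "n": int(len(vals)),
                         "mean": float(vals.mean()) if len(vals) else np.nan,
                         "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan})
    return pd.DataFrame(rows)


def impute_mcmc(ratings: pd.DataFrame, **kwargs):  # pragma: no cover - stub
    """Multiple imputation via MCMC (robustness check; not implemented).

    The study protocol names this only as an off-the-shelf sensitivity
    analysis whose results matched LOCF; this package exposes the hook
    but does not reproduce it.
    """
    raise NotImplementedError(
        "MCMC multiple imputation is a named robustness check, not part of "
        "this package; use locf() for the primary analysis")
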