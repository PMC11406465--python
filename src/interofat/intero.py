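"""Scoring of the two cardiac interoception tasks.

Heartbeat tracking task (HTT): the participant silently counts felt
heartbeats during a handful of timed windows while the true count is read
from a pulse oximeter.  Per-window accuracy is

    I_acc = 1 - |n_real - n_reported| / ((n_real + n_reported) / 2)

i.e. the absolute counting error normalised by the mean of the two counts,
averaged over windows.  The score is 1 for a perfect report and is *not*
clamped below: reporting zero beats gives -1.  Interoceptive insight for
the HTT is the within-participant Pearson correlation between per-window
confidence (0-10 visual analogue scale) and per-window accuracy.

Heartbeat discrimination task (HDT): on each trial a tone train is played
either synchronously or asynchronously with the heartbeat and the
participant judges which.  Accuracy is the fraction of correct judgements;
insight is the area under the type-2 ROC relating trial-by-trial
confidence to correctness, computed by the rank (Mann-Whitney)
formulation with half credit for ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyInputError,
    InsufficientTrialsError,
    InvalidInputError,
    UndefinedScoreError,
)

logger = logging.getLogger(__name__)

CONFIDENCE_VAS_MAX = 10.0


@dataclass(frozen=True)
class HTTTrial:
    """One heartbeat-tracking window: true and reported counts plus a 0-10 confidence."""

    duration_s: float
    nbeats_real: int
    nbeats_reported: int
    confidence: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InvalidInputError(f"duration_s must be positive, got {self.duration_s}")
        if self.nbeats_real < 0 or self.nbeats_reported < 0:
            raise InvalidInputError("beat counts must be non-negative")
        if not 0.0 <= self.confidence <= CONFIDENCE_VAS_MAX:
            raise InvalidInputError(
                f"confidence must lie in [0, {CONFIDENCE_VAS_MAX}], got {self.confidence}"
            )


@dataclass(frozen=True)
class HDTTrial:
    """One heartbeat-discrimination trial: tone type, judgement and confidence."""

    tone_type: str  # "synchronous" | "asynchronous"
    judgement: str
    confidence: float

    def __post_init__(self) -> None:
        for field in (self.tone_type, self.judgement):
            if field not in ("synchronous", "asynchronous"):
                raise InvalidInputError(f"tone/judgement must be (a)synchronous, got {field!r}")
        if not 0.0 <= self.confidence <= CONFIDENCE_VAS_MAX:
            raise InvalidInputError(
                f"confidence must lie in [0, {CONFIDENCE_VAS_MAX}], got {self.confidence}"
            )

    @property
    def correct(self) -> bool:
        return self.judgement == self.tone_type


@dataclass(frozen=True)
class InteroScores:
    """Per-subject summary of both tasks.

    ``htt_insight_r`` and ``hdt_insight_auc`` are NaN when the statistic is
    undefined (zero variance; all trials correct or all incorrect).
    ``htt_insight_low_trial`` flags correlations estimated from fewer than
    10 windows, which are known to be unstable.
    """

    htt_accuracy: float
    htt_insight_r: float
    hdt_accuracy: float
    hdt_insight_auc: float
    htt_insight_low_trial: bool = False


def htt_trial_accuracy(nbeats_real: int, nbeats_reported: int) -> float:
    """Per-window heartbeat-counting accuracy.

    Returns ``1 - |real - reported| / ((real + reported)/2)``.  The absolute
    error is used so under- and over-reporting are penalised alike; the
    score is not clamped and reaches -1 when one count is zero.
    """
    if nbeats_real < 0 or nbeats_reported < 0:
        raise InvalidInputError("beat counts must be non-negative")
    total = nbeats_real + nbeats_reported
    if total == 0:
        raise UndefinedScoreError("accuracy undefined when both counts are zero")
    return 1.0 - abs(nbeats_real - nbeats_reported) / (total / 2.0)


def htt_accuracy(trials: Sequence[HTTTrial]) -> float:
    """Mean per-window accuracy; windows with two zero counts are skipped with a warning."""
    scores = []
    for i, t in enumerate(trials):
        try:
            scores.append(htt_trial_accuracy(t.nbeats_real, t.nbeats_reported))
        except UndefinedScoreError:
            logger.warning("skipping HTT window %d: both counts zero", i)
    if not scores:
        raise EmptyInputError("no scorable HTT windows")
    return float(np.mean(scores))


def htt_insight(trials: Sequence[HTTTrial]) -> float:
    """Pearson correlation between window confidence and window accuracy.

    Requires at least 3 scorable windows; returns NaN when either the
    confidence or accuracy vector is constant (correlation undefined).
    """
    pairs = []
    for i, t in enumerate(trials):
        try:
            acc = htt_trial_accuracy(t.nbeats_real, t.nbeats_reported)
        except UndefinedScoreError:
            logger.warning("skipping HTT window %d: both counts zero", i)
            continue
        pairs.append((t.confidence, acc))
    if len(pairs) < 3:
        raise InsufficientTrialsError(
            f"need >=3 scorable windows for a confidence-accuracy correlation, got {len(pairs)}"
        )
    conf, acc = map(np.asarray, zip(*pairs))
    if np.ptp(conf) == 0 or np.ptp(acc) == 0:
        logger.warning("HTT insight undefined: zero variance in confidence or accuracy")
        return float("nan")
    return float(stats.pearsonr(conf, acc).statistic)


def hdt_accuracy(trials: Sequence[HDTTrial]) -> float:
    """Fraction of correct synchrony judgements."""
    if len(trials) == 0:
        raise EmptyInputError("no HDT trials")
    return float(np.mean([t.correct for t in trials]))


def hdt_insight(trials: Sequence[HDTTrial]) -> float:
    """Type-2 ROC area relating confidence to correctness.

    Rank (Mann-Whitney) formulation: the probability that a randomly drawn
    correct trial carries strictly higher confidence than a randomly drawn
    incorrect one, with ties counting one half.  Equals the trapezoidal
    area under the empirical type-2 ROC swept over confidence thresholds.
    NaN when all trials are correct or all incorrect.
    """
    if len(trials) == 0:
        raise EmptyInputError("no HDT trials")
    correct = np.array([t.correct for t in trials], dtype=bool)
    conf = np.array([t.confidence for t in trials], dtype=float)
    n_pos = int(correct.sum())
    n_neg = int((~correct).sum())
    if n_pos == 0 or n_neg == 0:
        logger.warning(
            "HDT insight undefined: %s trials only", "correct" if n_neg == 0 else "incorrect"
        )
        return float("nan")
    ranks = stats.rankdata(conf)  # midranks handle ties -> half credit
    auc = (ranks[correct].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


def score_subject(
    htt_trials: Sequence[HTTTrial],
    hdt_trials: Sequence[HDTTrial],
    low_trial_threshold: int = 10,
) -> InteroScores:
    """Score both tasks for one subject into a single summary row."""
    return InteroScores(
        htt_accuracy=htt_accuracy(htt_trials),
        htt_insight_r=htt_insight(htt_trials),
        hdt_accuracy=hdt_accuracy(hdt_trials),
        hdt_insight_auc=hdt_insight(hdt_trials),
        htt_insight_low_trial=len(htt_trials) < low_trial_threshold,
    )


# ---------------------------------------------------------------------------
# Tabular I/O.  Trial tables are tidy CSV/TSV, one row per trial:
#   HTT: subject_id, duration_s, nbeats_real, nbeats_reported, confidence
#   HDT: subject_id, tone_type, judgement, confidence
# ---------------------------------------------------------------------------

HTT_COLUMNS = ["subject_id", "duration_s", "nbeats_real", "nbeats_reported", "confidence"]
HDT_COLUMNS = ["subject_id", "tone_type", "judgement", "confidence"]


def _read_table(path, required: list[str]) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    return df


def read_htt_trials(path) -> dict[str, list[HTTTrial]]:
    """Read a tidy HTT trial table, returning trials grouped by subject."""
    df = _read_table(path, HTT_COLUMNS)
    out: dict[str, list[HTTTrial]] = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        out[str(sid)] = [
            HTTTrial(r.duration_s, int(r.nbeats_real), int(r.nbeats_reported), r.confidence)
            for r in grp.itertuples()
        ]
    return out


def read_hdt_trials(path) -> dict[str, list[HDTTrial]]:
    """Read a tidy HDT trial table, returning trials grouped by subject."""
    df = _read_table(path, HDT_COLUMNS)
    out: dict[str, list[HDTTrial]] = {}
    for sid, grp in df.groupby("subject_id", sort=False):
        out[str(sid)] = [HDTTrial(r.tone_type, r.judgement, r.confidence) for r in grp.itertuples()]
    return out


def score_table(
    htt_by_subject: dict[str, list[HTTTrial]],
    hdt_by_subject: dict[str, list[HDTTrial]],
) -> pd.DataFrame:
    """Score every subject appearing in both task tables into one row each."""
    rows = []
    for sid in htt_by_subject:
        if sid not in hdt_by_subject:
            logger.warning("subject %s has HTT but no HDT trials; skipped", sid)
            continue
        s = score_subject(htt_by_subject[sid], hdt_by_subject[sid])
        rows.append(
            {
                "subject_id": sid,
                "htt_accuracy": s.htt_accuracy,
                "htt_insight_r": s.htt_insight_r,
                "hdt_accuracy": s.hdt_accuracy,
                "hdt_insight_auc": s.hdt_insight_auc,
                "htt_insight_low_trial": s.htt_insight_low_trial,
            }
        )
    if not rows:
        raise EmptyInputError("no subjects with both HTT and HDT trials")
    return pd.DataFrame(rows)
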