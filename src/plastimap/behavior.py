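"""Single-pellet reaching-task scoring and learning rates.

A training session is a list of discrete trials (one pellet each).  A trial
is successful when the pellet is retrieved with the trained forelimb and no
abnormal behavior (trials flagged ``invalid`` never count as successes).
Three session scores are computed:

* success: percent of completed trials that were valid successes,
* accuracy: percent of valid successes relative to the total number of
  reach attempts pooled over the successful trials (ratio of sums),
* first-attempt success: percent of completed trials succeeding on the
  first reach.

The per-animal learning rate is the slope ``b`` of an ordinary
least-squares fit of ``success_pct = a + b * ln(day)`` over training days
(day index starting at 1).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "SessionScore",
    "score_session",
    "learning_rate",
    "trials_from_frame",
    "score_table",
]


@dataclass(frozen=True)
class TrialRecord:
    """One reach-to-grasp trial."""

    success: bool
    attempts: int = 1
    invalid: bool = False

    def __post_init__(self) -> None:
        if self.attempts < 1:
            raise ValueError(f"attempts must be >= 1, got {self.attempts}")

    @property
    def valid_success(self) -> bool:
        """Success that counts: invalid trials never do."""
        return self.success and not self.invalid


@dataclass(frozen=True)
class SessionScore:
    """Scores for one animal-day; percentages in [0, 100].

    ``accuracy_pct`` is NaN when the session has no valid success (no
    attempts to normalize by).  ``accuracy_per_trial_pct`` is the
    alternative convention (mean over successful trials of 100/attempts),
    reported alongside so either reading of "normalized by the number of
    attempts" can be checked.
    """

    day: int
    n_trials: int
    success_pct: float
    accuracy_pct: float
    first_attempt_pct: float
    accuracy_per_trial_pct: float = float("nan")


def score_session(trials: Sequence[TrialRecord], day: int = 0) -> SessionScore:
    """Score one session of trials.

    Raises
    ------
    ValueError
        On an empty session.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("cannot score an empty session")
    n = len(trials)
    successes = [t for t in trials if t.valid_success]
    n_succ = len(successes)
    success_pct = 100.0 * n_succ / n
    first_attempt_pct = 100.0 * sum(1 for t in successes if t.attempts == 1) / n
    if n_succ:
        total_attempts = sum(t.attempts for t in successes)
        accuracy_pct = 100.0 * n_succ / total_attempts
        accuracy_per_trial = 100.0 * float(
            np.mean([1.0 / t.attempts for t in successes])
        )
    else:
        accuracy_pct = float("nan")
        accuracy_per_trial = float("nan")
    return SessionScore(
        day=day,
        n_trials=n,
        success_pct=success_pct,
        accuracy_pct=accuracy_pct,
        first_attempt_pct=first_attempt_pct,
        accuracy_per_trial_pct=accuracy_per_trial,
    )


def learning_rate(scores: Iterable[SessionScore]) -> float:
    """Slope of the logarithmic learning-curve fit.

    Fits ``success_pct = a + b * ln(day)`` by OLS over the animal's
    sessions and returns ``b`` (percentage points per log-day).

    Raises
    ------
    ValueError
        With fewer than 3 sessions, or any day < 1 (the logarithm needs
        training-day indices starting at 1).
    """
    scores = sorted(scores, key=lambda s: s.day)
    if len(scores) < 3:
        raise ValueError(f"need >= 3 sessions for a learning rate, got {len(scores)}")
    days = np.array([s.day for s in scores], dtype=float)
    if np.any(days < 1):
        raise ValueError("training days must be >= 1 for the logarithmic fit")
    y = np.array([s.success_pct for s in scores], dtype=float)
    slope, _ = np.polyfit(np.log(days), y, 1)
    return float(slope)


def trials_from_frame(frame: pd.DataFrame) -> dict[str, dict[int, list[TrialRecord]]]:
    """Group a per-trial table into {animal: {day: [TrialRecord, ...]}}.

    Expects columns ``animal, day, success, attempts, invalid`` (extra
    columns ignored; ``invalid`` optional, defaulting to valid).
    """
    if "invalid" not in frame.columns:
        frame = frame.assign(invalid=False)
    out: dict[str, dict[int, list[TrialRecord]]] = {}
    for (animal, day), grp in frame.groupby(["animal", "day"], sort=True):
        recs = [
            TrialRecord(bool(s), int(a), bool(i))
            for s, a, i in zip(grp["success"], grp["attempts"], grp["invalid"])
        ]
        out.setdefault(str(animal), {})[int(day)] = recs
    return out


def score_table(sessions: dict[str, dict[int, list[TrialRecord]]]) -> pd.DataFrame:
    """Score every animal-day and append each animal's learning rate.

    Animals with fewer than 3 sessions get a NaN learning rate rather
    than an error, so mixed cohorts tabulate cleanly.
    """
    rows = []
    for animal, by_day in sessions.items():
        scores = [score_session(trials, day=day) for day, trials in sorted(by_day.items())]
        try:
            rate = learning_rate(scores)
        except ValueError:
            rate = math.nan
        for s in scores:
            rows.append(
                {
                    "animal": animal,
                    "day": s.day,
                    "n_trials": s.n_trials,
                    "success_pct": s.success_pct,
                    "accuracy_pct": s.accuracy_pct,
                    "first_attempt_pct": s.first_attempt_pct,
                    "accuracy_per_trial_pct": s.accuracy_per_trial_pct,
                    "learning_rate": rate,
                }
            )
    return pd.DataFrame(rows)
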