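"""Domain types and I/O for signaled active avoidance session data.

A training session exposes a rat to 30 tone (CS) trials; shuttling during the
tone is scored as an avoidance response (1), failure to shuttle as an escape
(0).  Sessions are summarised into three 10-trial bins per day, so an animal
trained for ``D`` days carries ``T = 3 * D`` avoidance scores, each an integer
count in ``[0, 10]``.  Inter-trial crossings (ITRs) are recorded once per
session as a nonnegative count and may be missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TRIALS_PER_SESSION = 30
TRIALS_PER_BIN = 10
BINS_PER_DAY = 3

SESSION_COLUMNS = ["animal_id", "day", "trial", "avoided", "itr_count"]


class MalformedSessionError(ValueError):
    """Raised when a session log violates the 30-trials-per-day contract."""


@dataclass(frozen=True)
class SessionLog:
    """One animal's record for one day of training.

    Parameters
    ----------
    animal_id : str
        Unique animal identifier.
    day : int
        Training day, 1-based.
    trial_outcomes : tuple of int
        Exactly 30 binary indicators in trial order; 1 = shuttled during the
        CS (avoidance), 0 = escape.
    itr_count : int or None
        Number of non-CS shuttles that session; ``None`` when not recorded.
    pavlovian_lead_trial : bool
        True only for day 1, marking the unscored Pavlovian lead trial that
        precedes the 30 scorable avoidance trials.
    """

    animal_id: str
    day: int
    trial_outcomes: tuple[int, ...]
    itr_count: int | None = None
    pavlovian_lead_trial: bool = False

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError(f"day must be >= 1, got {self.day}")
        if len(self.trial_outcomes) != TRIALS_PER_SESSION:
            raise MalformedSessionError(
                f"animal {self.animal_id!r} day {self.day}: expected "
                f"{TRIALS_PER_SESSION} scorable trials, got "
                f"{len(self.trial_outcomes)}"
            )
        if any(o not in (0, 1) for o in self.trial_outcomes):
            raise ValueError(
                f"animal {self.animal_id!r} day {self.day}: trial outcomes "
                "must be 0/1"
            )
        if self.itr_count is not None and self.itr_count < 0:
            raise ValueError("itr_count must be nonnegative")


@dataclass(frozen=True)
class BinnedTrajectory:
    """Per-animal avoidance scores, three 10-trial bins per training day."""

    animal_id: str
    scores: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.scores) % BINS_PER_DAY != 0 or len(self.scores) == 0:
            raise ValueError(
                f"trajectory length must be a positive multiple of "
                f"{BINS_PER_DAY}, got {len(self.scores)}"
            )
        if any(not (0 <= s <= TRIALS_PER_BIN) for s in self.scores):
            raise ValueError("scores must lie in [0, 10]")

    @property
    def n_days(self) -> int:
        return len(self.scores) // BINS_PER_DAY

    def day_end_scores(self) -> tuple[int, ...]:
        """Score of the last 10-trial bin of each day."""
        return self.scores[BINS_PER_DAY - 1 :: BINS_PER_DAY]


@dataclass
class Cohort:
    """A set of binned trajectories with aligned per-day ITR counts.

    ``itr_matrix`` is ``n x D`` with ``NaN`` marking sessions where ITRs were
    not recorded (never encoded as 0).  ``true_classes`` is populated by the
    synthetic generator for recovery scoring and absent for real data.
    """

    animals: list[BinnedTrajectory]
    itr_matrix: np.ndarray
    true_classes: np.ndarray | None = None
    baseline_crossings: np.ndarray | None = None
    class_labels: list[str] | None = None

    def __post_init__(self) -> None:
        ids = [a.animal_id for a in self.animals]
        if len(set(ids)) != len(ids):
            raise ValueError("animal identifiers must be unique")
        lengths = {len(a.scores) for a in self.animals}
        if len(lengths) > 1:
            raise ValueError(f"ragged trajectory lengths: {sorted(lengths)}")
        self.itr_matrix = np.asarray(self.itr_matrix, dtype=float)
        if self.animals:
            if self.itr_matrix.shape != (self.n, self.D):
                raise ValueError(
                    f"itr_matrix shape {self.itr_matrix.shape} does not match "
                    f"({self.n}, {self.D})"
                )
        if self.true_classes is not None:
            self.true_classes = np.asarray(self.true_classes, dtype=int)
            if len(self.true_classes) != self.n:
                raise ValueError("true_classes length mismatch")

    @property
    def n(self) -> int:
        return len(self.animals)

    @property
    def D(self) -> int:
        return self.animals[0].n_days if self.animals else 0

    @property
    def T(self) -> int:
        return self.D * BINS_PER_DAY

    @property
    def animal_ids(self) -> list[str]:
        return [a.animal_id for a in self.animals]


def bin_trials(logs: Iterable[SessionLog]) -> BinnedTrajectory:
    """Aggregate one animal's session logs into 10-trial avoidance bins.

    Bin ``j`` of day ``d`` counts the avoidance responses among trials
    ``10(j-1)+1 .. 10j`` of that day; output length is ``3 * D``.

    Raises
    ------
    MalformedSessionError
        If days are missing or duplicated (each day must contribute exactly
        30 scorable trials).
    """
    logs = sorted(logs, key=lambda s: s.day)
    if not logs:
        raise MalformedSessionError("no sessions supplied")
    animal_ids = {s.animal_id for s in logs}
    if len(animal_ids) > 1:
        raise ValueError(f"logs mix animals: {sorted(animal_ids)}")
    animal_id = logs[0].animal_id
    days = [s.day for s in logs]
    if days != list(range(1, len(days) + 1)):
        raise MalformedSessionError(
            f"animal {animal_id!r}: days {days} are not consecutive from 1"
        )
    scores: list[int] = []
    for session in logs:
        outcomes = session.trial_outcomes  # length 30, validated on creation
        for j in range(BINS_PER_DAY):
            scores.append(
                int(sum(outcomes[j * TRIALS_PER_BIN : (j + 1) * TRIALS_PER_BIN]))
            )
    return BinnedTrajectory(animal_id=animal_id, scores=tuple(scores))


def bin_cohort(
    logs: Iterable[SessionLog],
    true_classes: dict[str, int] | None = None,
) -> Cohort:
    """Group session logs by animal and assemble a :class:`Cohort`."""
    by_animal: dict[str, list[SessionLog]] = {}
    for s in logs:
        by_animal.setdefault(s.animal_id, []).append(s)
    animals = []
    itr_rows = []
    for animal_id in sorted(by_animal):
        sessions = sorted(by_animal[animal_id], key=lambda s: s.day)
        animals.append(bin_trials(sessions))
        itr_rows.append(
            [math.nan if s.itr_count is None else float(s.itr_count) for s in sessions]
        )
    tc = None
    if true_classes is not None:
        tc = np.array([true_classes[a.animal_id] for a in animals])
    return Cohort(animals=animals, itr_matrix=np.array(itr_rows), true_classes=tc)


def to_matrix(cohort: Cohort) -> tuple[np.ndarray, list[str]]:
    """Stack a cohort's trajectories into an ``n x T`` integer matrix.

    Row ``i`` holds animal ``i``'s scores in chronological bin order; the
    returned id list is aligned with the rows.  Ragged trajectory lengths are
    rejected at :class:`Cohort` construction.
    """
    if cohort.n == 0:
        return np.empty((0, 0), dtype=int), []
    mat = np.array([a.scores for a in cohort.animals], dtype=int)
    return mat, cohort.animal_ids


def read_session_csv(path) -> list[SessionLog]:
    """Parse a long-format session CSV into validated :class:`SessionLog` rows.

    Expected header: ``animal_id, day, trial, avoided, itr_count`` with one
    row per trial; ``itr_count`` may be repeated on every trial row or given
    only on trial 1 (blank elsewhere).  Blank ``itr_count`` throughout a day
    means the session's ITRs were not recorded.
    """
    df = pd.read_csv(path, dtype={"animal_id": str})
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session CSV missing columns: {missing}")
    if df.empty:
        return []
    bad = df[~df["avoided"].isin([0, 1])]
    if not bad.empty:
        row = int(bad.index[0]) + 2  # 1-based, counting the header line
        raise ValueError(
            f"non-binary 'avoided' value {bad['avoided'].iloc[0]!r} at "
            f"file row {row}"
        )
    dup = df.duplicated(subset=["animal_id", "day", "trial"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ValueError(f"duplicate (animal, day, trial) at file row {row}")
    logs = []
    for (animal_id, day), grp in df.groupby(["animal_id", "day"], sort=True):
        grp = grp.sort_values("trial")
        itr_vals = grp["itr_count"].dropna().unique()
        if len(itr_vals) > 1:
            raise ValueError(
                f"inconsistent itr_count for animal {animal_id!r} day {day}"
            )
        itr = int(itr_vals[0]) if len(itr_vals) else None
        logs.append(
            SessionLog(
                animal_id=str(animal_id),
                day=int(day),
                trial_outcomes=tuple(int(v) for v in grp["avoided"]),
                itr_count=itr,
            )
        )
    return logs


def write_session_csv(logs: Sequence[SessionLog], path) -> None:
    """Write session logs in the long format read by :func:`read_session_csv`."""
    records = []
    for s in sorted(logs, key=lambda s: (s.animal_id, s.day)):
        for t, outcome in enumerate(s.trial_outcomes, start=1):
            records.append(
                {
                    "animal_id": s.animal_id,
                    "day": s.day,
                    "trial": t,
                    "avoided": outcome,
                    "itr_count": s.itr_count if t == 1 else None,
                }
            )
    df = pd.DataFrame(records, columns=SESSION_COLUMNS)
    df["itr_count"] = df["itr_count"].astype("Int64")
    df.to_csv(path, index=False)


def write_binned_csv(cohort: Cohort, path) -> None:
    """Write trajectories in wide form: ``animal_id, bin_1 .. bin_T``."""
    mat, ids = to_matrix(cohort)
    df = pd.DataFrame(mat, columns=[f"bin_{j + 1}" for j in range(mat.shape[1])])
    df.insert(0, "animal_id", ids)
    df.to_csv(path, index=False)


def read_binned_csv(path) -> Cohort:
    """Read a wide binned CSV back into a :class:`Cohort` (ITRs absent)."""
    df = pd.read_csv(path, dtype={"animal_id": str})
    bins = [c for c in df.columns if c.startswith("bin_")]
    animals = [
        BinnedTrajectory(
            animal_id=str(r["animal_id"]),
            scores=tuple(int(r[c]) for c in bins),
        )
        for _, r in df.iterrows()
    ]
    D = len(bins) // BINS_PER_DAY
    itr = np.full((len(animals), D), np.nan)
    return Cohort(animals=animals, itr_matrix=itr)
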