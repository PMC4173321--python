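"""Posterior class assignment, phenotype labels, and the acquisition rule.

Acquisition of active avoidance within a single training day is identified
by avoiding on at least 50% of the day's last 10 trials (day-end bin score
>= 5), maintained through every subsequent day.  The day the criterion is
first met (and held) maps a trajectory to a phenotype: day 1 -> Rapid
Avoider, day 2-3 -> Modal, day 4 or later -> Slow, never -> Non-Avoider.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import BINS_PER_DAY, BinnedTrajectory, Cohort, to_matrix
from .model_selection import entropy
from .pgmm import MixtureFit, PiecewiseDesign

__all__ = [
    "PhenotypeAssignment",
    "assign_modal",
    "acquisition_day",
    "label_classes",
    "assign_phenotypes",
    "day_end_summary",
    "ACQUISITION_THRESHOLD",
]

logger = logging.getLogger(__name__)

ACQUISITION_THRESHOLD = 5  # >= 50% of the last 10 trials of a day
LOW_ENTROPY_THRESHOLD = 0.6

PHENOTYPES = ("Rapid", "Modal", "Slow", "Non")


@dataclass(frozen=True)
class PhenotypeAssignment:
    animal_id: str
    modal_class: int
    posterior_max: float
    label: str
    acquisition_day: int | None


def assign_modal(fit: MixtureFit) -> pd.DataFrame:
    """Modal (highest-posterior) class per animal.

    Ties go to the lower class index (logged).  Emits a warning when the
    fit's entropy is low: saving hard assignments then introduces
    misclassification error into downstream analyses.
    """
    P = fit.posteriors
    modal = np.argmax(P, axis=1)  # argmax returns the first (lowest) index on ties
    pmax = P[np.arange(len(P)), modal]
    n_ties = int(np.sum(np.sum(np.isclose(P, pmax[:, None]), axis=1) > 1))
    if n_ties:
        logger.info("%d posterior ties broken toward the lower class index", n_ties)
    ent = entropy(P)
    if fit.K >= 2 and ent < LOW_ENTROPY_THRESHOLD:
        warnings.warn(
            f"classification entropy {ent:.2f} < {LOW_ENTROPY_THRESHOLD}: "
            "saved modal assignments are unreliable",
            UserWarning,
            stacklevel=2,
        )
    return pd.DataFrame({"modal_class": modal, "posterior_max": pmax})


def acquisition_day(trajectory) -> int | None:
    """Earliest day whose day-end bin meets the >=50% criterion and every
    later day's day-end bin does too; ``None`` if never.

    Accepts a :class:`BinnedTrajectory` or a raw score sequence of length
    ``3 * D`` (model-implied mean trajectories are allowed, hence floats).
    """
    scores = np.asarray(
        trajectory.scores if isinstance(trajectory, BinnedTrajectory) else trajectory,
        dtype=float,
    )
    if scores.ndim != 1 or len(scores) % BINS_PER_DAY != 0:
        raise ValueError("trajectory length must be a multiple of 3")
    day_end = scores[BINS_PER_DAY - 1 :: BINS_PER_DAY]
    met = day_end >= ACQUISITION_THRESHOLD
    # earliest day from which the criterion holds on every later day
    for d in range(len(met)):
        if met[d:].all():
            return d + 1
    return None


def _label_from_day(day: int | None) -> str:
    if day is None:
        return "Non"
    if day == 1:
        return "Rapid"
    if day <= 3:
        return "Modal"
    return "Slow"


def label_classes(fit: MixtureFit, design: PiecewiseDesign | None = None) -> dict[int, str]:
    """Map fitted class indices to phenotype labels via the acquisition rule.

    Each class's model-implied mean trajectory is scored with
    :func:`acquisition_day`.  When two classes collide on a label (for
    example two classes that never meet the criterion), all four labels are
    reassigned by ordering classes on (acquisition day, then descending
    end-of-training mean) — the class that never acquires but ends higher is
    the Slow, not the Non, Avoider — and the collision is logged.  For
    K != 4 the classes keep generic names annotated with their acquisition
    day.
    """
    design = design or fit.design
    implied = np.clip(fit.class_means @ design.loadings.T, 0.0, 10.0)
    days = [acquisition_day(implied[k]) for k in range(fit.K)]
    if fit.K != len(PHENOTYPES):
        return {
            k: f"Class{k + 1}(acq={'none' if d is None else d})"
            for k, d in enumerate(days)
        }
    labels = {k: _label_from_day(d) for k, d in enumerate(days)}
    if len(set(labels.values())) == len(PHENOTYPES):
        return labels
    # collision: rank by earliest acquisition, ties toward higher end mean
    end_means = implied[:, -1]
    order = sorted(
        range(fit.K),
        key=lambda k: (days[k] if days[k] is not None else np.inf, -end_means[k]),
    )
    resolved = {k: PHENOTYPES[rank] for rank, k in enumerate(order)}
    logger.warning(
        "phenotype label collision (%s); resolved by acquisition/end-mean "
        "ordering to %s",
        {k: labels[k] for k in sorted(labels)},
        {k: resolved[k] for k in sorted(resolved)},
    )
    return resolved


def assign_phenotypes(
    fit: MixtureFit, cohort: Cohort, design: PiecewiseDesign | None = None
) -> pd.DataFrame:
    """Per-animal assignment table: modal class, posterior, phenotype label,
    and the animal's own acquisition day from its observed trajectory."""
    modal = assign_modal(fit)
    labels = label_classes(fit, design)
    return pd.DataFrame(
        {
            "animal_id": cohort.animal_ids,
            "modal_class": modal["modal_class"],
            "posterior_max": modal["posterior_max"],
            "label": [labels[int(k)] for k in modal["modal_class"]],
            "acquisition_day": [acquisition_day(a) for a in cohort.animals],
        }
    )


def day_end_summary(cohort: Cohort, assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-class, per-day mean, SD and 95% normal CI of day-end bin scores.

    Classes with fewer than two animals report NaN SD/CI.
    """
    mat, ids = to_matrix(cohort)
    if list(assignments["animal_id"]) != ids:
        raise ValueError("assignments do not cover the cohort in order")
    day_end = mat[:, BINS_PER_DAY - 1 :: BINS_PER_DAY]
    rows = []
    for label, grp in assignments.groupby("label", sort=True):
        idx = grp.index.to_numpy()
        sub = day_end[idx]
        n = len(idx)
        for d in range(cohort.D):
            mean = float(sub[:, d].mean())
            if n >= 2:
                sd = float(sub[:, d].std(ddof=1))
                half = 1.96 * sd / np.sqrt(n)
                lo, hi = mean - half, mean + half
            else:
                sd = lo = hi = float("nan")
            rows.append(
                {
                    "label": label, "day": d + 1, "n": n,
                    "mean": mean, "sd": sd, "ci_low": lo, "ci_high": hi,
                }
            )
    return pd.DataFrame(rows)
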