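"""Trial-level generative model of avoidance-learning cohorts.

Each animal belongs to one of four latent phenotypes (Rapid, Modal, Slow,
Non-Avoider) whose mean avoidance trajectories follow a piecewise-linear
growth curve: an intercept at the first 10-trial bin plus one slope per
training day, two bin steps per day.  The packaged Study-1 (n = 81, 3 days)
and Study-2 (n = 186, 5 days) configurations carry the published four-class
solutions as their generating truth, so parameter-recovery experiments have
a known target.

Per-bin avoidance counts are Binomial(10, mean/10) by default (the natural
noise model for a count of 10 Bernoulli trials); a Gaussian mode matches the
fitted model's own residual assumption for calibration work.  Per-day
inter-trial crossing (ITR) counts are Poisson with class-specific day means;
the published figures give only the qualitative ordering of those means, so
the defaults are illustrative and configurable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .data_model import (
    BINS_PER_DAY,
    TRIALS_PER_BIN,
    BinnedTrajectory,
    Cohort,
    SessionLog,
)

__all__ = [
    "ClassSpec",
    "CohortConfig",
    "study1_config",
    "study2_config",
    "class_mean_trajectory",
    "simulate_cohort",
    "simulate_trial_logs",
    "write_truth_csv",
]


@dataclass(frozen=True)
class ClassSpec:
    """One latent class: mixing weight, growth factors, ITR day means."""

    label: str
    proportion: float
    intercept: float
    day_slopes: tuple[float, ...]
    itr_day_means: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError(f"proportion must be in [0,1], got {self.proportion}")


@dataclass
class CohortConfig:
    """Full generative specification of a synthetic cohort.

    ``random_intercept_sd`` and ``random_day1_slope_sd`` add subject-level
    Gaussian deviations to the class intercept and day-1 slope, mirroring the
    growth factors left free in the larger study; all later slopes are fixed.
    """

    n: int
    D: int
    classes: list[ClassSpec]
    noise_model: str = "binomial"
    gaussian_sd: float = 1.0
    random_intercept_sd: float = 0.0
    random_day1_slope_sd: float = 0.0
    baseline_crossing_mean: float = 20.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.D < 1:
            raise ValueError("D must be >= 1")
        total = sum(c.proportion for c in self.classes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, expected 1")
        if self.noise_model not in ("binomial", "gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        for c in self.classes:
            if len(c.day_slopes) != self.D:
                raise ValueError(
                    f"class {c.label!r} has {len(c.day_slopes)} day slopes, "
                    f"expected {self.D}"
                )

    @property
    def T(self) -> int:
        return self.D * BINS_PER_DAY

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = json.load(fh)
        raw["classes"] = [
            ClassSpec(
                label=c["label"],
                proportion=c["proportion"],
                intercept=c["intercept"],
                day_slopes=tuple(c["day_slopes"]),
                itr_day_means=tuple(c.get("itr_day_means", ())),
            )
            for c in raw["classes"]
        ]
        return cls(**raw)


def study1_config() -> CohortConfig:
    """Packaged 3-day cohort: published 4-class solution, fixed effects only.

    Proportions 20/21/37/22% with the published intercepts and per-day
    slopes; no subject-level variation (pure latent class growth analysis).
    ITR day means are illustrative (ITRs were not consistently recorded in
    the 3-day study).
    """
    classes = [
        ClassSpec("Non", 0.20, 1.22, (0.29, -0.43, -0.27), (0.3, 0.5, 2.0)),
        ClassSpec("Slow", 0.21, 1.91, (0.97, 0.28, 0.29), (1.0, 2.0, 4.0)),
        ClassSpec("Modal", 0.37, 1.47, (1.39, 1.69, 0.85), (3.0, 5.0, 7.0)),
        ClassSpec("Rapid", 0.22, 3.93, (2.12, 0.33, 0.13), (8.0, 9.0, 9.0)),
    ]
    return CohortConfig(n=81, D=3, classes=classes)


def study2_config() -> CohortConfig:
    """Packaged 5-day cohort: published 4-class solution with free intercept
    and day-1 slope.

    Proportions 16/9/50/25% with the published growth-factor means; subject
    SDs 0.8 (intercept) and 0.2 (day-1 slope) supply the free-effect
    variation.  ITR day means encode the published qualitative pattern:
    Rapid high from day 1, Non-Avoiders near zero until day 3, the other two
    classes intermediate.
    """
    classes = [
        ClassSpec(
            "Non", 0.16, 0.50, (0.15, 0.57, -0.23, -0.03, -0.26),
            (0.3, 0.5, 2.0, 3.0, 3.0),
        ),
        ClassSpec(
            "Slow", 0.09, 0.43, (0.70, 0.29, 0.04, 2.11, 1.04),
            (1.0, 2.0, 4.0, 6.0, 7.0),
        ),
        ClassSpec(
            "Modal", 0.50, 1.39, (0.43, 2.14, 0.70, 0.13, 0.01),
            (3.0, 5.0, 7.0, 7.0, 7.0),
        ),
        ClassSpec(
            "Rapid", 0.25, 4.15, (1.62, 0.29, 0.09, 0.11, -0.07),
            (8.0, 9.0, 9.0, 8.0, 8.0),
        ),
    ]
    return CohortConfig(
        n=186,
        D=5,
        classes=classes,
        random_intercept_sd=0.8,
        random_day1_slope_sd=0.2,
    )


def _trajectory(intercept: float, day_slopes, D: int) -> np.ndarray:
    """Unclipped piecewise mean: bins 0,1,2 of day d step by slope_d."""
    means = np.empty(D * BINS_PER_DAY)
    level = intercept
    t = 0
    for d in range(D):
        for j in range(BINS_PER_DAY):
            means[t] = level + j * day_slopes[d]
            t += 1
        level += (BINS_PER_DAY - 1) * day_slopes[d]
    return means


def class_mean_trajectory(spec: ClassSpec, D: int) -> np.ndarray:
    """Model-implied mean score per bin for one class, clipped to [0, 10].

    Bin ``j`` (1-based) of day ``d`` has mean
    ``intercept + sum_{d' < d} 2 * slope_{d'} + (j - 1) * slope_d``.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    return np.clip(_trajectory(spec.intercept, spec.day_slopes, D), 0.0, TRIALS_PER_BIN)


def _draw_structure(config: CohortConfig, rng: np.random.Generator):
    """Draw class memberships and subject-level bin probabilities."""
    props = np.array([c.proportion for c in config.classes])
    z = rng.choice(len(props), size=config.n, p=props)
    b_int = rng.normal(0.0, config.random_intercept_sd, size=config.n)
    b_s1 = rng.normal(0.0, config.random_day1_slope_sd, size=config.n)
    mean_rows = np.empty((config.n, config.T))
    for i in range(config.n):
        spec = config.classes[z[i]]
        slopes = (spec.day_slopes[0] + b_s1[i],) + tuple(spec.day_slopes[1:])
        mean_rows[i] = np.clip(
            _trajectory(spec.intercept + b_int[i], slopes, config.D),
            0.0,
            TRIALS_PER_BIN,
        )
    return z, mean_rows


def simulate_cohort(config: CohortConfig, seed: int | None = None) -> Cohort:
    """Simulate a cohort of binned trajectories with class-linked ITR counts.

    Identical seeds give identical cohorts; the returned :class:`Cohort`
    carries ``true_classes`` (indices into ``config.classes``) for recovery
    scoring, plus Poisson baseline (habituation) crossing counts shared
    across classes.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    width = max(3, len(str(max(config.n, 1))))
    if config.n == 0:
        return Cohort(
            animals=[],
            itr_matrix=np.empty((0, config.D)),
            true_classes=np.empty(0, dtype=int),
            class_labels=[c.label for c in config.classes],
        )
    z, mean_rows = _draw_structure(config, rng)
    if config.noise_model == "binomial":
        scores = rng.binomial(TRIALS_PER_BIN, mean_rows / TRIALS_PER_BIN)
    else:
        raw = rng.normal(mean_rows, config.gaussian_sd)
        scores = np.clip(np.rint(raw), 0, TRIALS_PER_BIN).astype(int)
    animals = [
        BinnedTrajectory(f"rat{str(i + 1).zfill(width)}", tuple(int(s) for s in scores[i]))
        for i in range(config.n)
    ]
    itr = np.empty((config.n, config.D))
    for i in range(config.n):
        day_means = config.classes[z[i]].itr_day_means
        if len(day_means) != config.D:
            day_means = tuple([1.0] * config.D)
        itr[i] = rng.poisson(np.asarray(day_means, dtype=float))
    baseline = rng.poisson(config.baseline_crossing_mean, size=config.n).astype(float)
    return Cohort(
        animals=animals,
        itr_matrix=itr,
        true_classes=z,
        baseline_crossings=baseline,
        class_labels=[c.label for c in config.classes],
    )


def simulate_trial_logs(
    config: CohortConfig, seed: int | None = None
) -> tuple[list[SessionLog], dict[str, int]]:
    """Simulate trial-level session logs (Bernoulli per trial within bins).

    Binning these logs reproduces the binomial bin-score distribution of
    :func:`simulate_cohort` exactly in law.  Returns the logs plus a map of
    animal id to true class index.  Requires the binomial noise model.
    """
    if config.noise_model != "binomial":
        raise ValueError("trial-level simulation requires the binomial noise model")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    width = max(3, len(str(max(config.n, 1))))
    z, mean_rows = _draw_structure(config, rng)
    logs: list[SessionLog] = []
    truth: dict[str, int] = {}
    for i in range(config.n):
        animal_id = f"rat{str(i + 1).zfill(width)}"
        truth[animal_id] = int(z[i])
        itr_means = config.classes[z[i]].itr_day_means
        for d in range(config.D):
            p_bins = mean_rows[i, d * BINS_PER_DAY : (d + 1) * BINS_PER_DAY] / 10.0
            outcomes = tuple(
                int(o)
                for j in range(BINS_PER_DAY)
                for o in rng.binomial(1, p_bins[j], size=TRIALS_PER_BIN)
            )
            itr = int(rng.poisson(itr_means[d])) if len(itr_means) == config.D else None
            logs.append(
                SessionLog(
                    animal_id=animal_id,
                    day=d + 1,
                    trial_outcomes=outcomes,
                    itr_count=itr,
                    pavlovian_lead_trial=(d == 0),
                )
            )
    return logs, truth


def write_truth_csv(cohort: Cohort, path) -> None:
    """Write ``animal_id, true_class`` for recovery scoring."""
    import pandas as pd

    if cohort.true_classes is None:
        raise ValueError("cohort carries no true class labels")
    pd.DataFrame(
        {"animal_id": cohort.animal_ids, "true_class": cohort.true_classes}
    ).to_csv(path, index=False)
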