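"""Post-hoc group analyses of inter-trial crossing (ITR) behavior.

Once animals carry phenotype assignments, their per-day ITR counts are
compared across classes with a repeated-measures MANOVA (Wilks' lambda on
within-subject difference scores, class as the between-subjects factor),
Fisher's LSD pairwise comparisons per day, and a one-way ANOVA on baseline
(habituation) crossings.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = ["RmAnovaResult", "rm_manova", "lsd_pairwise", "oneway_anova"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RmAnovaResult:
    effect: str
    wilks_lambda: float
    F: float
    df1: float
    df2: float
    p: float


def _rao_f(lam: float, p: int, q: int, v: float) -> tuple[float, float, float, float]:
    """Rao's F approximation for Wilks' lambda (exact when min(p, q) <= 2)."""
    if p * p + q * q - 5 > 0:
        t = np.sqrt((p * p * q * q - 4.0) / (p * p + q * q - 5.0))
    else:
        t = 1.0
    m = v - (p - q + 1.0) / 2.0
    df1 = float(p * q)
    df2 = m * t - (p * q - 2.0) / 2.0
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1
    return F, df1, df2, float(stats.f.sf(F, df1, df2))


def rm_manova(itr_matrix: np.ndarray, groups) -> dict[str, RmAnovaResult]:
    """Repeated-measures MANOVA on per-day ITR counts.

    Forms ``days - 1`` successive-difference variables per animal and tests,
    on an effects-coded linear model with class as the between-subjects
    factor, the within-subject time effect (intercept of the difference
    model) and the time-by-class interaction, each via Wilks' lambda from
    the hypothesis/error cross-product matrices with Rao's F.  Animals with
    any missing ITR day are dropped (complete-case, logged).
    """
    Y = np.asarray(itr_matrix, dtype=float)
    groups = np.asarray(groups)
    if Y.ndim != 2 or Y.shape[0] != len(groups):
        raise ValueError("itr_matrix rows must align with groups")
    keep = ~np.isnan(Y).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("rm_manova: dropped %d animals with missing ITR days", n_dropped)
    Y, groups = Y[keep], groups[keep]
    levels = sorted(pd.unique(groups).tolist())
    g = len(levels)
    days = Y.shape[1]
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = {lv: int(np.sum(groups == lv)) for lv in levels}
    for lv, c in counts.items():
        if c < days + 1:
            raise ValueError(
                f"group {lv!r} has {c} complete animals; need at least {days + 1}"
            )

    # successive-difference within-subject variables
    C = np.zeros((days - 1, days))
    for j in range(days - 1):
        C[j, j], C[j, j + 1] = -1.0, 1.0
    Z = Y @ C.T  # n x (days-1)

    # effects-coded between-subjects design: intercept + (g-1) deviations
    n = len(groups)
    X = np.ones((n, g))
    for j, lv in enumerate(levels[:-1]):
        X[:, j + 1] = (groups == lv).astype(float) - (groups == levels[-1]).astype(float)

    XtX = X.T @ X
    B = linalg.solve(XtX, X.T @ Z)  # g x (days-1)
    resid = Z - X @ B
    E = resid.T @ resid
    v = n - g  # error df
    if np.linalg.matrix_rank(E) < days - 1:
        raise linalg.LinAlgError(
            "singular error matrix; a group's difference scores are degenerate"
        )

    def wilks_for(L: np.ndarray) -> tuple[float, int]:
        LB = L @ B
        M = linalg.solve(L @ linalg.solve(XtX, L.T), LB)
        H = LB.T @ M
        lam = linalg.det(E) / linalg.det(E + H)
        return float(lam), L.shape[0]

    results = {}
    for name, L in (
        ("time", np.eye(g)[:1]),
        ("time_by_group", np.eye(g)[1:]),
    ):
        lam, q = wilks_for(L)
        F, df1, df2, p = _rao_f(lam, days - 1, q, v)
        results[name] = RmAnovaResult(name, lam, F, df1, df2, p)
    return results


def lsd_pairwise(itr_matrix: np.ndarray, groups, day: int | None = None) -> pd.DataFrame:
    """Fisher's LSD pairwise group comparisons of per-day ITR means.

    Per day, all group pairs are compared with t-tests using the pooled
    within-group error term (df = n - g) and uncorrected p-values, the
    standard follow-up to a significant omnibus test.  Groups with fewer
    than two complete animals are excluded with a warning.
    """
    Y = np.asarray(itr_matrix, dtype=float)
    groups = np.asarray(groups)
    days = range(Y.shape[1]) if day is None else [day - 1]
    rows = []
    for d in days:
        col = Y[:, d]
        keep = ~np.isnan(col)
        colk, gk = col[keep], groups[keep]
        levels = [lv for lv in sorted(pd.unique(gk).tolist()) if np.sum(gk == lv) >= 2]
        dropped = set(pd.unique(gk)) - set(levels)
        if dropped:
            logger.warning("LSD day %d: excluded groups with n < 2: %s", d + 1, dropped)
        if len(levels) < 2:
            raise ValueError("need at least 2 usable groups")
        ns = {lv: int(np.sum(gk == lv)) for lv in levels}
        means = {lv: float(colk[gk == lv].mean()) for lv in levels}
        sse = sum(float(((colk[gk == lv] - means[lv]) ** 2).sum()) for lv in levels)
        df = sum(ns.values()) - len(levels)
        mse = sse / df
        for a, b in itertools.combinations(levels, 2):
            diff = means[a] - means[b]
            se = np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
            t = diff / se if se > 0 else 0.0
            p = 2.0 * stats.t.sf(abs(t), df) if se > 0 else 1.0
            rows.append(
                {
                    "day": d + 1, "group_a": a, "group_b": b,
                    "mean_diff": diff, "t": t, "df": df, "p": p,
                }
            )
    return pd.DataFrame(rows)


def oneway_anova(values, groups) -> tuple[float, int, int, float]:
    """One-way ANOVA (F, df_between, df_within, p) on baseline crossings."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == lv] for lv in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least 2 members")
    F, p = stats.f_oneway(*samples)
    df1 = len(levels) - 1
    df2 = len(values) - len(levels)
    return float(F), df1, df2, float(p)
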