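"""Class enumeration: information criteria, entropy, likelihood-ratio tests.

Choosing the number of trajectory classes follows the standard mixture
workflow: fit K = 1..K_max, compare information criteria (AIC, BIC,
sample-size-adjusted BIC), classification entropy, an analytic
Lo-Mendell-Rubin-style likelihood ratio test, and the parametric bootstrap
likelihood ratio test (BLRT), then retain the most parsimonious solution.
The retention rule codifies the informal "IC reductions + LRT + parsimony"
reasoning deterministically: the largest K whose BIC improvement over K - 1
exceeds a threshold, whose BLRT rejects, and whose smallest class is not
spuriously small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .pgmm import EstimationError, MixtureFit, ModelSpec, PiecewiseDesign, fit_multistart

__all__ = [
    "information_criteria",
    "entropy",
    "lmrt",
    "blrt",
    "enumerate_classes",
    "LrtResult",
    "BlrtResult",
    "SelectionReport",
]


def information_criteria(loglik: float, n_params: int, n: int) -> tuple[float, float, float]:
    """(AIC, BIC, SSBIC) for a fitted model.

    AIC = -2LL + 2p; BIC = -2LL + p ln(n); SSBIC = -2LL + p ln((n + 2) / 24).
    """
    if n < 1 or n_params < 1:
        raise ValueError("need n >= 1 and n_params >= 1")
    d = -2.0 * loglik
    return (
        d + 2.0 * n_params,
        d + n_params * np.log(n),
        d + n_params * np.log((n + 2.0) / 24.0),
    )


def entropy(posteriors: np.ndarray) -> float:
    """Normalized classification entropy in [0, 1]; 1 = perfect separation.

    ``1 - sum_ik -p_ik ln p_ik / (n ln K)`` with ``p ln p = 0`` at ``p = 0``.
    Undefined (NaN) for K = 1.
    """
    P = np.asarray(posteriors, dtype=float)
    n, K = P.shape
    if K < 2:
        return float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    return float(1.0 + plogp.sum() / (n * np.log(K)))


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio test of K vs K - 1 classes (analytic approximation).

    ``p`` is the primary (adjusted) p-value; the unadjusted variant refers
    the raw 2*dLL to the same chi-square reference and both are retained so
    the variant used is always explicit.
    """

    stat: float  # 2 * dLL
    stat_adjusted: float
    df: int
    p_unadjusted: float
    p: float
    variant: str = "chi2(df=dparams), ad-hoc shrinkage c = 1 + 1/(df ln n)"


def lmrt(fit_K: MixtureFit, fit_Kminus1: MixtureFit, n: int) -> LrtResult:
    """Analytic likelihood-ratio test of K vs K - 1 classes.

    The 2*dLL statistic is referred to a chi-square with df equal to the
    parameter-count difference, with the ad-hoc small-sample shrinkage
    ``stat / (1 + 1/(df ln n))`` as the adjusted (primary) variant.  A
    negative dLL signals an optimization failure and yields NaN p-values
    with a warning.  Secondary to the bootstrap test for retention.
    """
    dll = fit_K.loglik - fit_Kminus1.loglik
    df = fit_K.n_params - fit_Kminus1.n_params
    if df < 1:
        raise ValueError("fits are not nested (nonpositive parameter difference)")
    if dll < -1e-8:
        warnings.warn(
            "K-class log-likelihood below the (K-1)-class one; "
            "multistart likely found a local optimum",
            RuntimeWarning,
            stacklevel=2,
        )
        return LrtResult(2 * dll, float("nan"), df, float("nan"), float("nan"))
    stat = max(2.0 * dll, 0.0)
    c = 1.0 + 1.0 / (df * np.log(n))
    stat_adj = stat / c
    return LrtResult(
        stat=stat,
        stat_adjusted=stat_adj,
        df=df,
        p_unadjusted=float(chi2.sf(stat, df)),
        p=float(chi2.sf(stat_adj, df)),
    )


@dataclass(frozen=True)
class BlrtResult:
    p: float
    lr_observed: float
    lr_bootstrap: np.ndarray
    n_draws: int
    n_failed: int


def _simulate_from_fit(fit: MixtureFit, rng: np.random.Generator) -> np.ndarray:
    """Parametric draw of an n x T dataset from a fitted Gaussian mixture."""
    from .pgmm import _marginal_cov  # shared covariance helper

    z = rng.choice(fit.K, size=fit.n, p=fit.proportions / fit.proportions.sum())
    mu = fit.implied_means()
    S = _marginal_cov(fit.design, fit.residual_var, fit.random_cov, fit.random_factors)
    chol = np.linalg.cholesky(S)
    eps = rng.standard_normal((fit.n, fit.design.T)) @ chol.T
    return mu[z] + eps


def blrt(
    Y: np.ndarray,
    design: PiecewiseDesign,
    spec_Kminus1: ModelSpec,
    spec_K: ModelSpec,
    B: int = 99,
    seed: int | None = None,
    fit_Kminus1: MixtureFit | None = None,
    fit_K: MixtureFit | None = None,
    bootstrap_starts: int = 10,
) -> BlrtResult:
    """Parametric bootstrap likelihood ratio test of K vs K - 1 classes.

    Fits both models to the data; then for each of ``B`` draws simulates a
    dataset from the fitted (K-1)-class model, refits both (with a reduced
    multistart budget) and records the bootstrap LR.  The p-value is the
    exact Monte-Carlo count ``(1 + #{LR* >= LR}) / (B + 1)``.  Draws whose
    refit fails are discarded and logged; more than 20% failures is an error.
    """
    if B < 19:
        raise ValueError("B must be >= 19 for a meaningful bootstrap p-value")
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)
    if fit_Kminus1 is None:
        fit_Kminus1 = fit_multistart(Y, design, replace(spec_Kminus1, seed=int(rng.integers(2**31))))
    if fit_K is None:
        fit_K = fit_multistart(Y, design, replace(spec_K, seed=int(rng.integers(2**31))))
    lr_obs = max(2.0 * (fit_K.loglik - fit_Kminus1.loglik), 0.0)

    boot_spec0 = replace(
        spec_Kminus1, n_starts=bootstrap_starts, n_final_starts=2,
        tol=1e-5, max_iter=200,
    )
    boot_spec1 = replace(
        spec_K, n_starts=bootstrap_starts, n_final_starts=2,
        tol=1e-5, max_iter=200,
    )
    lrs = []
    n_failed = 0
    for _ in range(B):
        Yb = _simulate_from_fit(fit_Kminus1, rng)
        try:
            f0 = fit_multistart(Yb, design, replace(boot_spec0, seed=int(rng.integers(2**31))))
            f1 = fit_multistart(Yb, design, replace(boot_spec1, seed=int(rng.integers(2**31))))
        except EstimationError:
            n_failed += 1
            continue
        lrs.append(max(2.0 * (f1.loglik - f0.loglik), 0.0))
    if n_failed > 0.2 * B:
        raise EstimationError(f"{n_failed}/{B} bootstrap refits failed")
    lrs = np.asarray(lrs)
    Beff = len(lrs)
    p = (1.0 + float(np.sum(lrs >= lr_obs))) / (Beff + 1.0)
    return BlrtResult(p=p, lr_observed=lr_obs, lr_bootstrap=lrs, n_draws=Beff, n_failed=n_failed)


@dataclass
class SelectionReport:
    """Per-K enumeration table plus the retained solution and its rationale."""

    table: pd.DataFrame
    retained_K: int
    rationale: str
    fits: dict[int, MixtureFit]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __str__(self) -> str:  # human-readable report
        lines = [self.table.to_string(index=False), "", f"retained K = {self.retained_K}", self.rationale]
        return "\n".join(lines)


def enumerate_classes(
    Y: np.ndarray,
    design: PiecewiseDesign,
    base_spec: ModelSpec,
    K_max: int = 5,
    B: int = 49,
    seed: int | None = None,
    bic_drop_threshold: float = 6.0,
    alpha: float = 0.05,
    min_class_proportion: float = 0.05,
    run_blrt: bool = True,
) -> SelectionReport:
    """Fit K = 1..K_max and retain a class count by an explicit rule.

    Retained K is the largest K such that (a) BIC improves on K - 1 by more
    than ``bic_drop_threshold``, (b) the BLRT rejects at ``alpha`` and (c)
    the smallest class holds at least ``min_class_proportion`` of the
    sample; K = 1 if no K qualifies.  A K whose fit fails is marked failed
    and enumeration continues.
    """
    if K_max < 2:
        raise ValueError("K_max must be >= 2")
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    fits: dict[int, MixtureFit] = {}
    prev_fit = None
    prev_ll = None
    for K in range(1, K_max + 1):
        spec = replace(base_spec, K=K, seed=int(rng.integers(2**31)))
        row: dict = {"K": K}
        try:
            fit = fit_multistart(Y, design, spec)
        except EstimationError as exc:
            row.update({"failed": True, "note": str(exc)})
            rows.append(row)
            prev_fit = None
            continue
        fits[K] = fit
        aic, bic, ssbic = information_criteria(fit.loglik, fit.n_params, n)
        row.update(
            {
                "failed": False,
                "LL": fit.loglik,
                "n_params": fit.n_params,
                "AIC": aic,
                "BIC": bic,
                "SSBIC": ssbic,
                "entropy": entropy(fit.posteriors),
                "min_class_prop": float(fit.proportions.min()),
                "replicated_LL": bool(fit.replicated_loglik),
            }
        )
        if prev_ll is not None and fit.loglik < prev_ll - 1e-6 * (1 + abs(prev_ll)):
            row["ll_nonmonotone_flag"] = True  # multistart diagnostic, not a failure
        if prev_fit is not None:
            row["lmrt_p"] = lmrt(fit, prev_fit, n).p
            if run_blrt:
                res = blrt(
                    Y, design,
                    replace(base_spec, K=K - 1), replace(base_spec, K=K),
                    B=B, seed=int(rng.integers(2**31)),
                    fit_Kminus1=prev_fit, fit_K=fit,
                )
                row["blrt_p"] = res.p
        rows.append(row)
        prev_fit = fit
        prev_ll = fit.loglik

    table = pd.DataFrame(rows)
    retained = 1
    bounds = []
    for i, row in table.iterrows():
        K = int(row["K"])
        if K == 1 or row.get("failed", True):
            continue
        prev = table[table["K"] == K - 1]
        if prev.empty or prev.iloc[0].get("failed", True):
            continue
        bic_drop = float(prev.iloc[0]["BIC"]) - float(row["BIC"])
        blrt_ok = (not run_blrt) or (row.get("blrt_p", 1.0) < alpha)
        ok = (
            bic_drop > bic_drop_threshold
            and blrt_ok
            and row["min_class_prop"] >= min_class_proportion
        )
        if ok:
            retained = K
        else:
            reasons = []
            if bic_drop <= bic_drop_threshold:
                reasons.append(f"BIC drop {bic_drop:.1f} <= {bic_drop_threshold}")
            if not blrt_ok:
                reasons.append(f"BLRT p {row.get('blrt_p', float('nan')):.3f} >= {alpha}")
            if row["min_class_prop"] < min_class_proportion:
                reasons.append(
                    f"smallest class {100 * row['min_class_prop']:.1f}% < "
                    f"{100 * min_class_proportion:.0f}%"
                )
            bounds.append(f"K={K} rejected: " + "; ".join(reasons))
    rationale = (
        f"retained K={retained} (largest K with BIC drop > {bic_drop_threshold}, "
        f"BLRT p < {alpha}, smallest class >= {100 * min_class_proportion:.0f}%)."
    )
    if bounds:
        rationale += " " + " ".join(bounds)
    return SelectionReport(table=table, retained_K=retained, rationale=rationale, fits=fits)
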