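"""Piecewise growth mixture model estimation.

The trajectory model is a finite mixture of multivariate-normal growth
curves.  With ``D`` training days and ``T = 3 * D`` bins, the loading matrix
``L`` maps growth factors (one intercept plus one slope per day) to the bin
means: within day ``d`` the day-``d`` slope column steps 0, 1, 2 and is then
held at 2, so a class's printed day slope is the mean increment per bin step
within that day.  Class ``k`` contributes

    y_i | k  ~  N(L m_k,  L_r V L_r' + s2 I)

where ``m_k`` are the class growth-factor means, ``V`` is the covariance of
the growth factors allowed subject-level variation (shared across classes;
empty set = latent class growth analysis, V = 0) and ``s2`` is a residual
variance shared across classes and bins.

Estimation is maximum likelihood by EM (generalized/ECM form: exact GLS
update of the class means given the current covariance, then one EM step on
the latent random effects for ``V`` and ``s2``; every sweep is monotone in
the observed log-likelihood).  Because mixture likelihoods are multimodal,
:func:`fit_multistart` runs many short EM passes from perturbed k-means
initializations and refines the best few to convergence, reporting whether
the top two final log-likelihoods replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg
from scipy.special import logsumexp
from scipy.stats import norm

from .data_model import BINS_PER_DAY

__all__ = [
    "PiecewiseDesign",
    "ModelSpec",
    "MixtureFit",
    "EstimationError",
    "build_design",
    "mixture_loglik",
    "em_fit",
    "fit_multistart",
    "standard_errors",
]

_LL_DECREASE_TOL = 1e-6  # relative slack for the EM monotonicity assertion


class EstimationError(RuntimeError):
    """Raised when no EM start yields a usable solution."""


@dataclass(frozen=True)
class PiecewiseDesign:
    """Loading matrix of the piecewise growth curve.

    Column 0 is the intercept (all ones); column ``d`` (1-based day) is 0
    before day ``d``, steps 0, 1, 2 across the day's three bins, and stays
    at 2 afterwards.
    """

    loadings: np.ndarray
    T: int
    D: int


def build_design(D: int) -> PiecewiseDesign:
    """Construct the ``T x (1 + D)`` piecewise loading matrix for ``D`` days."""
    if D < 1:
        raise ValueError(f"D must be >= 1, got {D}")
    T = BINS_PER_DAY * D
    L = np.zeros((T, 1 + D))
    L[:, 0] = 1.0
    for d in range(D):
        rows = slice(d * BINS_PER_DAY, (d + 1) * BINS_PER_DAY)
        L[rows, d + 1] = np.arange(BINS_PER_DAY)
        L[(d + 1) * BINS_PER_DAY :, d + 1] = BINS_PER_DAY - 1
    return PiecewiseDesign(loadings=L, T=T, D=D)


@dataclass(frozen=True)
class ModelSpec:
    """Estimation controls for one mixture fit.

    ``random_factors`` indexes growth factors with free (subject-level)
    variance: 0 = intercept, d = day-``d`` slope.  Empty means LCGA.
    """

    K: int
    random_factors: tuple[int, ...] = ()
    n_starts: int = 50
    n_final_starts: int = 5
    tol: float = 1e-7
    max_iter: int = 500
    short_iter: int = 30
    short_tol: float = 1e-5
    variance_floor: float = 1e-3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class MixtureFit:
    """A fitted K-class piecewise growth mixture solution."""

    class_means: np.ndarray  # K x (1 + D)
    proportions: np.ndarray  # K
    residual_var: float
    random_cov: np.ndarray | None  # r x r, shared across classes (None = LCGA)
    random_factors: tuple[int, ...]
    loglik: float
    posteriors: np.ndarray  # n x K
    n_params: int
    converged: bool
    design: PiecewiseDesign
    n: int
    ll_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    start_loglik_top2: tuple[float, float] | None = None
    class_mean_se: np.ndarray | None = None
    class_mean_z: np.ndarray | None = None
    class_mean_p: np.ndarray | None = None

    @property
    def K(self) -> int:
        return len(self.proportions)

    def implied_means(self) -> np.ndarray:
        """Model-implied K x T matrix of bin means."""
        return self.class_means @ self.design.loadings.T

    @property
    def replicated_loglik(self) -> bool | None:
        if self.start_loglik_top2 is None:
            return None
        a, b = self.start_loglik_top2
        return abs(a - b) < 1e-3


def _marginal_cov(
    design: PiecewiseDesign,
    residual_var: float,
    random_cov: np.ndarray | None,
    random_factors: tuple[int, ...],
) -> np.ndarray:
    S = residual_var * np.eye(design.T)
    if random_cov is not None and len(random_factors) > 0:
        Lr = design.loadings[:, list(random_factors)]
        S = S + Lr @ random_cov @ Lr.T
    return S


def _log_densities(Y, design, class_means, residual_var, random_cov, random_factors):
    """n x K matrix of per-class log normal densities (shared covariance)."""
    S = _marginal_cov(design, residual_var, random_cov, random_factors)
    try:
        cho = linalg.cho_factor(S, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - diagnostic path
        raise EstimationError(
            f"implied covariance not positive definite (residual_var="
            f"{residual_var:.3g}): {exc}"
        ) from exc
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    T = design.T
    mu = class_means @ design.loadings.T  # K x T
    logphi = np.empty((Y.shape[0], len(class_means)))
    for k in range(len(class_means)):
        diff = (Y - mu[k]).T  # T x n
        sol = linalg.cho_solve(cho, diff)
        quad = np.einsum("ij,ij->j", diff, sol)
        logphi[:, k] = -0.5 * (T * np.log(2 * np.pi) + logdet + quad)
    return logphi


def mixture_loglik(
    Y: np.ndarray,
    design: PiecewiseDesign,
    class_means: np.ndarray,
    proportions: np.ndarray,
    residual_var: float,
    random_cov: np.ndarray | None = None,
    random_factors: tuple[int, ...] = (),
) -> float:
    """Observed-data log-likelihood of the K-class trajectory mixture.

    ``LL = sum_i log sum_k pi_k N(y_i; L m_k, L_r V L_r' + s2 I)``.
    """
    Y = np.asarray(Y, dtype=float)
    class_means = np.atleast_2d(np.asarray(class_means, dtype=float))
    proportions = np.asarray(proportions, dtype=float)
    logphi = _log_densities(
        Y, design, class_means, residual_var, random_cov, random_factors
    )
    with np.errstate(divide="ignore"):
        logw = logphi + np.log(proportions)
    return float(np.sum(logsumexp(logw, axis=1)))


def _n_params(K: int, n_factors: int, r: int) -> int:
    return K * n_factors + (K - 1) + 1 + r * (r + 1) // 2


def _m_step_means(Y, design, resp, S):
    """Exact weighted-GLS update of the class means given covariance S."""
    L = design.loadings
    Sinv_L = linalg.solve(S, L, assume_a="pos")
    A = L.T @ Sinv_L  # (1+D) x (1+D)
    nk = resp.sum(axis=0)
    ybar = (resp.T @ Y) / nk[:, None]  # K x T
    return linalg.solve(A, Sinv_L.T @ ybar.T, assume_a="pos").T  # K x (1+D)


def em_fit(
    Y: np.ndarray,
    design: PiecewiseDesign,
    spec: ModelSpec,
    init_resp: np.ndarray,
    max_iter: int | None = None,
    tol: float | None = None,
) -> MixtureFit:
    """Run EM from an initial responsibility matrix (single start).

    The E-step computes responsibilities proportional to ``pi_k phi_k``; the
    M-step updates mixing proportions, class means (weighted GLS under the
    current covariance) and the variance components (one latent-random-effect
    EM step).  Iterates until the relative log-likelihood change falls below
    ``tol``; the log-likelihood is asserted nondecreasing every iteration.
    """
    Y = np.asarray(Y, dtype=float)
    n, T = Y.shape
    K = spec.K
    if n <= K:
        raise ValueError(f"need more animals ({n}) than classes ({K})")
    if T != design.T:
        raise ValueError(f"data has {T} bins but design expects {design.T}")
    max_iter = spec.max_iter if max_iter is None else max_iter
    tol = spec.tol if tol is None else tol
    rf = tuple(spec.random_factors)
    r = len(rf)

    resp = np.asarray(init_resp, dtype=float)
    resp = resp / resp.sum(axis=1, keepdims=True)

    # initial M-step with identity covariance (OLS means, pooled residual var)
    L = design.loadings
    props = resp.mean(axis=0)
    means = _m_step_means(Y, design, resp, np.eye(T))
    resid = Y[:, None, :] - (means @ L.T)[None, :, :]  # n x K x T
    s2 = max(float(np.einsum("ik,ikt->", resp, resid**2) / (n * T)), spec.variance_floor)
    V = 0.25 * np.eye(r) if r else None
    Lr = L[:, list(rf)] if r else None

    ll_prev = -np.inf
    trace = []
    converged = False
    for _ in range(max_iter):
        # E-step
        logphi = _log_densities(Y, design, means, s2, V, rf)
        with np.errstate(divide="ignore"):
            logw = logphi + np.log(np.maximum(props, 1e-300))
        lse = logsumexp(logw, axis=1)
        ll = float(np.sum(lse))
        if ll < ll_prev - _LL_DECREASE_TOL * (1.0 + abs(ll_prev)):
            raise EstimationError(
                f"EM log-likelihood decreased ({ll_prev:.6f} -> {ll:.6f})"
            )
        trace.append(ll)
        resp = np.exp(logw - lse[:, None])
        if ll_prev > -np.inf and abs(ll - ll_prev) <= tol * (1.0 + abs(ll_prev)):
            ll_prev = ll
            converged = True
            break
        ll_prev = ll

        # M-step
        props = resp.mean(axis=0)
        if np.any(props < 0.5 / n):
            warnings.warn(
                "degenerate class: a mixing proportion fell below 0.5/n",
                RuntimeWarning,
                stacklevel=2,
            )
        S = _marginal_cov(design, s2, V, rf)
        means = _m_step_means(Y, design, resp, S)
        resid = Y[:, None, :] - (means @ L.T)[None, :, :]
        if r:
            Vj = V + 1e-10 * np.eye(r)
            C = linalg.inv(Lr.T @ Lr / s2 + linalg.inv(Vj))
            G = Lr @ C / s2  # T x r
            m = np.einsum("ikt,tr->ikr", resid, G)  # n x K x r
            V = np.einsum("ik,ikr,iks->rs", resp, m, m) / n + C
            V = 0.5 * (V + V.T)
            # floor the random-factor variances to keep V invertible
            ev, U = np.linalg.eigh(V)
            V = U @ np.diag(np.maximum(ev, 1e-6)) @ U.T
            eps = resid - np.einsum("ikr,tr->ikt", m, Lr)
            s2 = float(
                (np.einsum("ik,ikt->", resp, eps**2) + n * np.trace(Lr @ C @ Lr.T))
                / (n * T)
            )
        else:
            s2 = float(np.einsum("ik,ikt->", resp, resid**2) / (n * T))
        s2 = max(s2, spec.variance_floor)

    return MixtureFit(
        class_means=means,
        proportions=props,
        residual_var=s2,
        random_cov=V,
        random_factors=rf,
        loglik=ll_prev,
        posteriors=resp,
        n_params=_n_params(K, design.loadings.shape[1], r),
        converged=converged,
        design=design,
        n=n,
        ll_trace=np.array(trace),
    )


def _canonicalize(fit: MixtureFit) -> MixtureFit:
    """Deterministic class order: ascending end-of-training implied mean."""
    end = fit.implied_means()[:, -1]
    order = np.argsort(end, kind="stable")
    fit.class_means = fit.class_means[order]
    fit.proportions = fit.proportions[order]
    fit.posteriors = fit.posteriors[:, order]
    if fit.class_mean_se is not None:
        fit.class_mean_se = fit.class_mean_se[order]
    return fit


def _kmeans_responsibilities(Y, K, random_state) -> np.ndarray:
    from sklearn.cluster import KMeans

    n = Y.shape[0]
    if K == 1:
        return np.ones((n, 1))
    km = KMeans(n_clusters=K, n_init=5, random_state=random_state)
    labels = km.fit_predict(Y)
    resp = np.zeros((n, K))
    resp[np.arange(n), labels] = 1.0
    return resp


def fit_multistart(Y: np.ndarray, design: PiecewiseDesign, spec: ModelSpec) -> MixtureFit:
    """Multi-start EM: short runs from perturbed k-means initializations,
    full refinement of the best few, best log-likelihood wins.

    Records the top two refined log-likelihoods; agreement within 1e-3 is the
    replicated-best-log-likelihood ("global solution") diagnostic.  Ties are
    broken toward the lowest start index.
    """
    if spec.n_starts < 2:
        raise ValueError("n_starts must be >= 2 for a multi-start fit")
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(spec.seed)
    base = _kmeans_responsibilities(Y, spec.K, int(rng.integers(2**31)))
    n = Y.shape[0]

    short: list[tuple[int, float, MixtureFit]] = []
    for s in range(spec.n_starts):
        if s == 0:
            resp0 = 0.95 * base + 0.05 / spec.K
        else:
            noise = rng.dirichlet(np.ones(spec.K), size=n)
            w = rng.uniform(0.2, 0.8)
            resp0 = (1 - w) * base + w * noise
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                f = em_fit(
                    Y, design, spec, resp0,
                    max_iter=spec.short_iter, tol=spec.short_tol,
                )
        except (EstimationError, linalg.LinAlgError):
            continue
        short.append((s, f.loglik, f))
    if not short:
        raise EstimationError("all EM starts failed")

    short.sort(key=lambda t: (-t[1], t[0]))
    finals: list[tuple[int, MixtureFit]] = []
    for s, _, f in short[: max(1, spec.n_final_starts)]:
        try:
            ff = em_fit(Y, design, spec, f.posteriors)
        except (EstimationError, linalg.LinAlgError):
            continue
        finals.append((s, ff))
    if not finals:
        raise EstimationError("all refinement starts failed")

    finals.sort(key=lambda t: (-t[1].loglik, t[0]))
    best = finals[0][1]
    lls = [f.loglik for _, f in finals]
    best.start_loglik_top2 = (lls[0], lls[1]) if len(lls) > 1 else (lls[0], np.nan)
    return _canonicalize(best)


# ---------------------------------------------------------------------------
# standard errors


def _pack(fit: MixtureFit) -> np.ndarray:
    parts = [fit.class_means.ravel()]
    if fit.K > 1:
        logits = np.log(fit.proportions[:-1]) - np.log(fit.proportions[-1])
        parts.append(logits)
    r = len(fit.random_factors)
    if r:
        cholV = np.linalg.cholesky(fit.random_cov + 1e-12 * np.eye(r))
        parts.append(cholV[np.tril_indices(r)])
    parts.append(np.array([np.log(fit.residual_var)]))
    return np.concatenate(parts)


def _loglik_of_theta(theta, Y, design, K, q, rf):
    r = len(rf)
    nm = K * q
    means = theta[:nm].reshape(K, q)
    pos = nm
    if K > 1:
        logits = np.concatenate([theta[pos : pos + K - 1], [0.0]])
        props = np.exp(logits - logsumexp(logits))
        pos += K - 1
    else:
        props = np.ones(1)
    V = None
    if r:
        tri = theta[pos : pos + r * (r + 1) // 2]
        Lch = np.zeros((r, r))
        Lch[np.tril_indices(r)] = tri
        V = Lch @ Lch.T
        pos += r * (r + 1) // 2
    s2 = float(np.exp(theta[pos]))
    return mixture_loglik(Y, design, means, props, s2, V, rf)


def standard_errors(fit: MixtureFit, Y: np.ndarray, design: PiecewiseDesign) -> np.ndarray:
    """Standard errors of the class growth-factor means from the inverse
    observed information (numerical Hessian at the optimum), plus Wald z and
    two-sided p-values stored on the fit.

    Returns the K x (1 + D) SE matrix; entries are NaN (with a warning) if
    the information matrix is singular.
    """
    if not fit.converged:
        raise ValueError("standard errors require a converged fit")
    Y = np.asarray(Y, dtype=float)
    theta = _pack(fit)
    K, q, rf = fit.K, fit.class_means.shape[1], fit.random_factors
    f = lambda t: _loglik_of_theta(t, Y, design, K, q, rf)

    p = len(theta)
    h = 1e-4 * (1.0 + np.abs(theta))
    H = np.empty((p, p))
    f0 = f(theta)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(theta + ei + ej) - f(theta + ei - ej)
                - f(theta - ei + ej) + f(theta - ei - ej)
            ) / (4 * h[i] * h[j])

    info = -H
    nm = K * q
    try:
        cov = linalg.inv(info)
        if np.any(np.diag(cov)[:nm] <= 0):
            raise linalg.LinAlgError("nonpositive variance estimate")
        se = np.sqrt(np.diag(cov)[:nm]).reshape(K, q)
    except linalg.LinAlgError:
        warnings.warn(
            "singular observed information; standard errors reported as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        se = np.full((K, q), np.nan)
    fit.class_mean_se = se
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fit.class_means / se
    fit.class_mean_z = z
    fit.class_mean_p = 2.0 * norm.sf(np.abs(z))
    return se
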