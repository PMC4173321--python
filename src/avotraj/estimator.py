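"""scikit-learn estimator facade over the piecewise growth mixture model."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, DensityMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data_model import BINS_PER_DAY
from .model_selection import entropy, information_criteria
from .pgmm import ModelSpec, build_design, fit_multistart, mixture_loglik, standard_errors


class PiecewiseGrowthMixture(DensityMixin, BaseEstimator):
    """Piecewise growth mixture model of avoidance-learning trajectories.

    Fits a K-class Gaussian mixture of piecewise-linear growth curves to an
    ``n x T`` matrix of binned avoidance scores (three 10-trial bins per
    training day, ``T = 3 * D``), with one slope per day and optional
    subject-level (random) variation on chosen growth factors.

    Parameters
    ----------
    n_classes : int
        Number of latent trajectory classes.
    random_factors : tuple of int
        Growth factors with free subject-level variance (0 = intercept,
        d = day-d slope).  Empty tuple = latent class growth analysis.
    n_starts, n_final_starts : int
        Multi-start budget: short EM runs, then full refinements of the best.
    tol, max_iter : float, int
        EM convergence controls (relative log-likelihood change).
    variance_floor : float
        Lower bound on the residual variance, blocking degenerate spikes.
    compute_se : bool
        Whether to compute growth-factor-mean standard errors (numerical
        observed information) after fitting.
    random_state : int or None
        Seed for k-means initialization and start perturbations.

    Attributes
    ----------
    means_ : ndarray of shape (K, 1 + D)
        Class growth-factor means (intercept, day slopes).
    mean_se_ : ndarray or None
        Matching standard errors when ``compute_se``.
    proportions_ : ndarray of shape (K,)
        Mixing proportions.
    residual_var_ : float
    random_cov_ : ndarray or None
        Shared covariance of the random growth factors.
    loglik_ : float
    posteriors_ : ndarray of shape (n, K)
        Training-set responsibilities.
    fit_result_ : MixtureFit
        Full fitted-solution record (trace, replication diagnostic, ...).

    Examples
    --------
    >>> from avotraj import simulate_cohort, study2_config, to_matrix
    >>> from avotraj.estimator import PiecewiseGrowthMixture
    >>> Y, _ = to_matrix(simulate_cohort(study2_config(), seed=7))
    >>> model = PiecewiseGrowthMixture(n_classes=4, random_factors=(0, 1),
    ...                                random_state=7).fit(Y)
    >>> model.proportions_.shape
    (4,)
    """

    def __init__(
        self,
        n_classes: int = 4,
        random_factors: tuple[int, ...] = (),
        n_starts: int = 50,
        n_final_starts: int = 5,
        tol: float = 1e-7,
        max_iter: int = 500,
        short_iter: int = 30,
        variance_floor: float = 1e-3,
        compute_se: bool = False,
        random_state: int | None = None,
    ):
        self.n_classes = n_classes
        self.random_factors = random_factors
        self.n_starts = n_starts
        self.n_final_starts = n_final_starts
        self.tol = tol
        self.max_iter = max_iter
        self.short_iter = short_iter
        self.variance_floor = variance_floor
        self.compute_se = compute_se
        self.random_state = random_state

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            K=self.n_classes,
            random_factors=tuple(self.random_factors),
            n_starts=self.n_starts,
            n_final_starts=self.n_final_starts,
            tol=self.tol,
            max_iter=self.max_iter,
            short_iter=self.short_iter,
            variance_floor=self.variance_floor,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if X.shape[1] % BINS_PER_DAY != 0:
            raise ValueError(
                f"number of columns ({X.shape[1]}) must be a multiple of "
                f"{BINS_PER_DAY} (three bins per training day)"
            )
        self.n_days_ = X.shape[1] // BINS_PER_DAY
        self.design_ = build_design(self.n_days_)
        fit = fit_multistart(X, self.design_, self._spec())
        if self.compute_se:
            standard_errors(fit, X, self.design_)
        self.fit_result_ = fit
        self.means_ = fit.class_means
        self.mean_se_ = fit.class_mean_se
        self.proportions_ = fit.proportions
        self.residual_var_ = fit.residual_var
        self.random_cov_ = fit.random_cov
        self.loglik_ = fit.loglik
        self.posteriors_ = fit.posteriors
        self.n_params_ = fit.n_params
        self.converged_ = fit.converged
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        """Posterior class responsibilities for new trajectories."""
        check_is_fitted(self, "means_")
        X = check_array(X, dtype=float)
        from scipy.special import logsumexp

        from .pgmm import _log_densities

        logphi = _log_densities(
            X, self.design_, self.means_, self.residual_var_,
            self.random_cov_, tuple(self.random_factors),
        )
        logw = logphi + np.log(self.proportions_)
        return np.exp(logw - logsumexp(logw, axis=1, keepdims=True))

    def predict(self, X):
        """Modal class index per trajectory."""
        return np.argmax(self.predict_proba(X), axis=1)

    def score(self, X, y=None):
        """Mean per-animal log-likelihood."""
        check_is_fitted(self, "means_")
        X = check_array(X, dtype=float)
        ll = mixture_loglik(
            X, self.design_, self.means_, self.proportions_,
            self.residual_var_, self.random_cov_, tuple(self.random_factors),
        )
        return ll / X.shape[0]

    def entropy(self) -> float:
        """Normalized classification entropy of the training posteriors."""
        check_is_fitted(self, "posteriors_")
        return entropy(self.posteriors_)

    def information_criteria(self) -> tuple[float, float, float]:
        """(AIC, BIC, SSBIC) of the fitted solution."""
        check_is_fitted(self, "loglik_")
        return information_criteria(self.loglik_, self.n_params_, len(self.posteriors_))
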