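"""Piecewise design, mixture likelihood, EM, multi-start, standard errors."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from avotraj import (
    ModelSpec,
    build_design,
    em_fit,
    fit_multistart,
    mixture_loglik,
    standard_errors,
)
from avotraj.pgmm import PiecewiseDesign


def _intercept_only(T):
    return PiecewiseDesign(loadings=np.ones((T, 1)), T=T, D=1)


class TestBuildDesign:
    @pytest.mark.parametrize("D", [1, 3, 5])
    def test_shape_and_intercept_column(self, D):
        d = build_design(D)
        assert d.loadings.shape == (3 * D, 1 + D)
        assert (d.loadings[:, 0] == 1).all()

    def test_day1_slope_column_D3(self):
        d = build_design(3)
        np.testing.assert_array_equal(
            d.loadings[:, 1], [0, 1, 2, 2, 2, 2, 2, 2, 2]
        )

    def test_single_day(self):
        d = build_design(1)
        np.testing.assert_array_equal(d.loadings, [[1, 0], [1, 1], [1, 2]])

    def test_slope_columns_zero_before_day_and_nondecreasing(self):
        d = build_design(5)
        assert d.T == 15 and d.loadings.shape[1] == 6
        for day in range(1, 6):
            col = d.loadings[:, day]
            assert (col[: (day - 1) * 3] == 0).all()
            assert (np.diff(col) >= 0).all() and col.max() == 2

    def test_invalid_days(self):
        with pytest.raises(ValueError):
            build_design(0)


class TestMixtureLoglik:
    def test_zero_residual_closed_form(self):
        design = _intercept_only(4)
        Y = np.full((7, 4), 2.5)
        s2 = 0.7
        ll = mixture_loglik(Y, design, [[2.5]], [1.0], s2)
        assert ll == pytest.approx(-(7 * 4 / 2) * np.log(2 * np.pi * s2))

    def test_matches_naive_per_observation_oracle(self, rng):
        design = build_design(2)
        K, n = 3, 12
        means = rng.normal(2, 1, size=(K, 3))
        props = rng.dirichlet(np.ones(K))
        V = np.array([[0.5, 0.1], [0.1, 0.2]])
        s2 = 0.8
        Y = rng.normal(3, 2, size=(n, 6))
        ll = mixture_loglik(Y, design, means, props, s2, V, (0, 1))
        # brute force: explicit per-animal, per-class density summation
        Lr = design.loadings[:, [0, 1]]
        S = Lr @ V @ Lr.T + s2 * np.eye(6)
        expected = 0.0
        for i in range(n):
            total = 0.0
            for k in range(K):
                mu = design.loadings @ means[k]
                total += props[k] * multivariate_normal.pdf(Y[i], mu, S)
            expected += np.log(total)
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_duplicating_rows_doubles_loglik(self, rng):
        design = build_design(1)
        Y = rng.normal(5, 1, size=(9, 3))
        args = (design, [[4.0, 0.5], [6.0, -0.5]], [0.4, 0.6], 1.3)
        assert mixture_loglik(np.vstack([Y, Y]), *args) == pytest.approx(
            2 * mixture_loglik(Y, *args)
        )


class TestEmFit:
    def test_k1_intercept_only_recovers_grand_mean(self, rng):
        Y = rng.normal(4.2, 1.0, size=(50, 6))
        design = _intercept_only(6)
        fit = em_fit(Y, design, ModelSpec(K=1), np.ones((50, 1)))
        assert fit.class_means[0, 0] == pytest.approx(Y.mean(), abs=1e-8)
        assert fit.converged

    def test_two_flat_classes_recovered(self, rng):
        design = _intercept_only(3)
        n = 200
        z = rng.random(n) < 0.5
        Y = np.where(z[:, None], 9.0, 1.0) + rng.normal(0, 0.5, size=(n, 3))
        spec = ModelSpec(K=2, n_starts=5, seed=0)
        fit = fit_multistart(Y, design, spec)
        means = np.sort(fit.class_means[:, 0])
        assert abs(means[0] - 1.0) < 0.15 and abs(means[1] - 9.0) < 0.15
        # canonical order is ascending mean, so class 0 is the low class;
        # compare against the realized (not population) mixing fraction
        assert abs(fit.proportions[0] - (1 - z.mean())) < 0.03

    def test_ll_trace_monotone(self, study2_fit):
        trace = study2_fit.ll_trace
        assert (np.diff(trace) >= -1e-6 * (1 + np.abs(trace[:-1]))).all()

    def test_posteriors_and_proportions_normalized(self, study2_fit):
        np.testing.assert_allclose(study2_fit.posteriors.sum(axis=1), 1.0, atol=1e-10)
        assert study2_fit.proportions.sum() == pytest.approx(1.0, abs=1e-10)

    def test_lcga_matches_independent_spherical_em(self, rng):
        """With no random factors the model is a spherical-residual Gaussian
        mixture over structured means; an independent bare-bones EM on the
        same data must reach the same solution."""
        design = _intercept_only(3)
        n = 120
        z = rng.random(n) < 0.4
        Y = np.where(z[:, None], 7.0, 2.0) + rng.normal(0, 1.0, size=(n, 3))
        fit = fit_multistart(Y, design, ModelSpec(K=2, n_starts=5, seed=3))
        assert fit.random_cov is None

        # independent oracle: EM for a 2-component equal-variance mixture of
        # flat trajectories, written from the textbook update equations
        mu = np.array([Y[:, 0].min(), Y[:, 0].max()])
        pi = np.array([0.5, 0.5])
        s2 = Y.var()
        for _ in range(500):
            logp = np.stack(
                [
                    np.log(pi[k])
                    + norm.logpdf(Y, mu[k], np.sqrt(s2)).sum(axis=1)
                    for k in range(2)
                ],
                axis=1,
            )
            m = logp.max(axis=1, keepdims=True)
            w = np.exp(logp - m)
            w /= w.sum(axis=1, keepdims=True)
            pi = w.mean(axis=0)
            mu = (w.T @ Y.mean(axis=1)) / w.sum(axis=0)
            resid2 = (Y[:, None, :] - mu[None, :, None]) ** 2
            s2 = (w[:, :, None] * resid2).sum() / (n * 3)
        oracle_mu = np.sort(mu)
        np.testing.assert_allclose(
            np.sort(fit.class_means[:, 0]), oracle_mu, atol=1e-4
        )
        assert fit.residual_var == pytest.approx(s2, abs=1e-4)

    def test_more_classes_than_animals_rejected(self, rng):
        Y = rng.normal(size=(3, 3))
        with pytest.raises(ValueError, match="more animals"):
            em_fit(Y, _intercept_only(3), ModelSpec(K=3), np.ones((3, 3)) / 3)


class TestMultistart:
    def test_seeded_determinism(self, rng):
        Y = rng.normal(5, 2, size=(60, 9))
        design = build_design(3)
        spec = ModelSpec(K=2, n_starts=8, seed=99)
        a = fit_multistart(Y, design, spec)
        b = fit_multistart(Y, design, spec)
        np.testing.assert_array_equal(a.class_means, b.class_means)
        assert a.loglik == b.loglik

    def test_single_start_rejected(self, rng):
        Y = rng.normal(size=(20, 3))
        with pytest.raises(ValueError, match="n_starts"):
            fit_multistart(Y, build_design(1), ModelSpec(K=2, n_starts=1))

    def test_replicated_ll_on_separated_classes(self, study2_fit):
        assert study2_fit.replicated_loglik

    def test_label_permutation_equivalence(self, rng):
        """Canonical class ordering makes the solution invariant to the
        arbitrary start labeling (different seeds, same optimum)."""
        design = _intercept_only(3)
        n = 150
        z = rng.random(n) < 0.5
        Y = np.where(z[:, None], 8.0, 1.0) + rng.normal(0, 0.6, size=(n, 3))
        fits = [
            fit_multistart(Y, design, ModelSpec(K=2, n_starts=6, seed=s))
            for s in (1, 2)
        ]
        np.testing.assert_allclose(
            fits[0].class_means, fits[1].class_means, atol=1e-5
        )
        np.testing.assert_allclose(fits[0].proportions, fits[1].proportions, atol=1e-5)


class TestStandardErrors:
    def test_iid_mean_se_closed_form(self, rng):
        n, T = 200, 3
        Y = rng.normal(5.0, 1.0, size=(n, T))
        design = _intercept_only(T)
        fit = fit_multistart(Y, design, ModelSpec(K=1, n_starts=2, seed=0))
        se = standard_errors(fit, Y, design)
        assert se[0, 0] == pytest.approx(
            np.sqrt(fit.residual_var / (n * T)), abs=1e-4
        )

    def test_se_halves_when_n_quadruples(self, rng):
        design = _intercept_only(3)
        Y = rng.normal(5.0, 1.2, size=(100, 3))
        Y4 = np.vstack([rng.normal(5.0, 1.2, size=(400, 3))])
        ses = []
        for data in (Y, Y4):
            fit = fit_multistart(data, design, ModelSpec(K=1, n_starts=2, seed=0))
            ses.append(standard_errors(fit, data, design)[0, 0])
        assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.15)

    def test_wald_p_is_one_for_zero_mean(self, rng):
        Y = rng.normal(0.0, 1.0, size=(150, 3))
        Y -= Y.mean()  # grand mean exactly zero
        design = _intercept_only(3)
        fit = fit_multistart(Y, design, ModelSpec(K=1, n_starts=2, seed=0))
        standard_errors(fit, Y, design)
        assert fit.class_mean_p[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_wald_p_matches_normal_survival(self, study2_fit, study2_matrix):
        se = standard_errors(study2_fit, study2_matrix, study2_fit.design)
        assert np.isfinite(se).all()
        z = study2_fit.class_means / se
        np.testing.assert_allclose(
            study2_fit.class_mean_p, 2 * norm.sf(np.abs(z)), atol=1e-12
        )
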