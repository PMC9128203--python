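"""Sum-of-single-effects engine: exact SER, IBSS, PIPs, credible sets."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, spearmanr

import hlafine as hf
from hlafine.susie import (
    SuSiE,
    compute_pips,
    extract_credible_sets,
    mean_impute,
    residualize_covariates,
    single_effect_regression,
    susie_fit,
)


def _center(X):
    return X - X.mean(axis=0)


class TestSingleEffectRegression:
    def test_zero_prior_variance_forces_null(self):
        rng = np.random.default_rng(0)
        X = _center(rng.normal(size=(30, 5)))
        r = rng.normal(size=30)
        alpha, mu, mu2, lbf = single_effect_regression(X, r, 1.0, 0.0)
        assert np.allclose(alpha, 0.2)
        assert np.allclose(mu, 0.0)
        assert lbf == pytest.approx(0.0, abs=1e-12)

    def test_matches_conjugate_marginal_likelihood_oracle(self):
        # independent route: multivariate-normal marginal per single-variant model
        rng = np.random.default_rng(1)
        n, p = 40, 4
        X = _center(rng.normal(size=(n, p)))
        r = 0.5 * X[:, 1] + rng.normal(size=n)
        sigma2, v0 = 1.3, 0.6
        alpha, mu, mu2, lbf = single_effect_regression(X, r, sigma2, v0)
        logml = np.array(
            [
                multivariate_normal.logpdf(
                    r, mean=np.zeros(n),
                    cov=sigma2 * np.eye(n) + v0 * np.outer(X[:, j], X[:, j]),
                )
                for j in range(p)
            ]
        )
        w = np.exp(logml - logml.max())
        w /= w.sum()
        assert np.abs(alpha - w).max() < 1e-12
        # posterior mean from conjugate normal-normal updating
        for j in range(p):
            d = X[:, j] @ X[:, j]
            bh = X[:, j] @ r / d
            s2 = sigma2 / d
            assert mu[j] == pytest.approx((v0 / (v0 + s2)) * bh, abs=1e-12)

    def test_duplicated_column_splits_alpha_evenly(self):
        rng = np.random.default_rng(2)
        x = _center(rng.normal(size=(50, 1)))
        X = np.hstack([x, x])
        r = 0.8 * x[:, 0] + rng.normal(size=50) * 0.3
        alpha, *_ = single_effect_regression(X, r, 1.0, 0.5)
        assert alpha[0] == pytest.approx(0.5, abs=1e-12)

    def test_invalid_variances_rejected(self):
        X = _center(np.random.default_rng(3).normal(size=(10, 2)))
        with pytest.raises(ValueError):
            single_effect_regression(X, np.zeros(10), 0.0, 0.5)
        with pytest.raises(ValueError):
            single_effect_regression(X, np.zeros(10), 1.0, -0.1)

    def test_zero_variance_column_gets_zero_alpha(self):
        rng = np.random.default_rng(4)
        X = _center(rng.normal(size=(30, 3)))
        X[:, 2] = 0.0
        with pytest.warns(UserWarning):
            alpha, *_ = single_effect_regression(X, rng.normal(size=30), 1.0, 0.5)
        assert alpha[2] == 0.0


class TestSuSiEFit:
    def test_single_strong_causal_recovered(self):
        rng = np.random.default_rng(5)
        X = rng.binomial(2, 0.4, size=(600, 50)).astype(float)
        y = 0.9 * X[:, 17] + rng.normal(size=600)
        fit = SuSiE(L=10).fit(X, y)
        assert len(fit.credible_sets_) == 1
        assert 17 in fit.credible_sets_[0].variant_indices
        assert fit.pip_[17] > 0.9

    def test_l1_pips_match_exhaustive_model_average(self):
        rng = np.random.default_rng(6)
        n, p = 100, 12
        X = rng.binomial(2, 0.3, size=(n, p)).astype(float)
        y = 0.4 * X[:, 3] + rng.normal(size=n)
        sigma2, v0 = 0.9, 0.4
        fit = SuSiE(
            L=1, prior_variance=v0, residual_variance=sigma2,
            estimate_prior_variance=False, estimate_residual_variance=False,
        ).fit(X, y)
        Xs = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()
        logml = np.array(
            [
                multivariate_normal.logpdf(
                    yc, mean=np.zeros(n),
                    cov=sigma2 * np.eye(n) + v0 * np.outer(Xs[:, j], Xs[:, j]),
                )
                for j in range(p)
            ]
        )
        w = np.exp(logml - logml.max())
        w /= w.sum()
        assert np.abs(fit.pip_ - w).max() < 1e-6

    def test_two_independent_signals_two_sets(self):
        rng = np.random.default_rng(7)
        X = rng.binomial(2, 0.4, size=(800, 60)).astype(float)
        y = 0.6 * X[:, 5] + 0.6 * X[:, 50] + rng.normal(size=800)
        fit = SuSiE(L=10).fit(X, y)
        assert len(fit.credible_sets_) == 2
        members = {j for cs in fit.credible_sets_ for j in cs.variant_indices}
        assert {5, 50} <= members

    def test_null_reports_no_credible_sets(self):
        rng = np.random.default_rng(8)
        zero_cs = 0
        n_rep = 40
        for _ in range(n_rep):
            X = rng.binomial(2, 0.3, size=(300, 100)).astype(float)
            y = rng.normal(size=300)
            fit = SuSiE(L=10).fit(X, y)
            if len(fit.credible_sets_) == 0:
                zero_cs += 1
        assert zero_cs >= 0.95 * n_rep

    def test_elbo_monotone(self):
        rng = np.random.default_rng(9)
        X = rng.binomial(2, 0.4, size=(300, 40)).astype(float)
        y = 0.4 * X[:, 3] - 0.3 * X[:, 25] + rng.normal(size=300)
        fit = SuSiE(L=5).fit(X, y)
        diffs = np.diff(fit.elbo_trace_)
        assert np.all(diffs > -1e-6)

    def test_column_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        X = rng.binomial(2, 0.4, size=(250, 20)).astype(float)
        y = 0.5 * X[:, 4] + rng.normal(size=250)
        perm = rng.permutation(20)
        f1 = SuSiE(L=3).fit(X, y)
        f2 = SuSiE(L=3).fit(X[:, perm], y)
        assert np.allclose(f2.pip_, f1.pip_[perm], atol=1e-8)
        assert np.allclose(f2.alpha_, f1.alpha_[:, perm], atol=1e-8)

    def test_non_finite_input_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            SuSiE().fit(X, np.zeros(10))

    def test_max_iter_reached_returns_unconverged_fit(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(200, 30))
        y = X[:, :3] @ np.array([0.3, -0.3, 0.2]) + rng.normal(size=200)
        fit = SuSiE(L=5, max_iter=1).fit(X, y)
        assert fit.converged_ is False
        assert fit.alpha_.shape == (5, 30)

    def test_binary_trait_pip_ranking_tracks_logistic_z(self):
        rng = np.random.default_rng(12)
        n, p = 1500, 15
        X = rng.binomial(2, 0.5, size=(n, p)).astype(float)
        eta = 0.35 * X[:, 2] - 0.3 * X[:, 9]
        y = (rng.random(n) < 1 / (1 + np.exp(-(eta - eta.mean())))).astype(float)
        fit = SuSiE(L=1, estimate_prior_variance=False).fit(X, y)
        zs = [abs(hf.fit_logistic(y, X[:, j]).beta / hf.fit_logistic(y, X[:, j]).se)
              for j in range(p)]
        rho = spearmanr(fit.alpha_[0], zs).statistic
        assert rho > 0.95

    def test_predict_returns_posterior_mean_fit(self):
        rng = np.random.default_rng(13)
        X = rng.binomial(2, 0.4, size=(500, 20)).astype(float)
        y = 1.0 * X[:, 7] + rng.normal(size=500) * 0.5
        fit = SuSiE(L=5).fit(X, y)
        r2 = np.corrcoef(fit.predict(X), y)[0, 1] ** 2
        assert r2 > 0.5

    def test_functional_wrapper_equivalent(self):
        rng = np.random.default_rng(14)
        X = rng.binomial(2, 0.4, size=(200, 10)).astype(float)
        y = 0.5 * X[:, 1] + rng.normal(size=200)
        f1 = susie_fit(X, y, L=4)
        f2 = SuSiE(L=4).fit(X, y)
        assert np.allclose(f1.pip_, f2.pip_)


class TestPips:
    def test_single_effect_pip_is_alpha_row(self):
        rng = np.random.default_rng(15)
        X = rng.binomial(2, 0.4, size=(300, 10)).astype(float)
        y = 0.6 * X[:, 2] + rng.normal(size=300)
        fit = SuSiE(L=1).fit(X, y)
        assert np.allclose(fit.pip_, fit.alpha_[0])

    def test_pip_combination_formula(self):
        # alpha 0.5 in each of two effects -> pip 0.75
        fit = SuSiE(L=2)
        fit.alpha_ = np.array([[0.5, 0.5], [0.5, 0.5]])
        fit.V_ = np.array([1.0, 1.0])
        fit.credible_sets_ = []
        pips = compute_pips(fit)
        assert pips[0] == pytest.approx(0.75)

    def test_all_null_effects_give_zero_pips(self):
        fit = SuSiE(L=2)
        fit.alpha_ = np.array([[0.5, 0.5], [0.5, 0.5]])
        fit.V_ = np.array([0.0, 0.0])
        fit.credible_sets_ = []
        assert np.allclose(compute_pips(fit), 0.0)


class TestCredibleSets:
    def _fit_with_alpha(self, alpha, X):
        fit = SuSiE(L=alpha.shape[0])
        fit.alpha_ = alpha
        fit.V_ = np.ones(alpha.shape[0])
        fit._Xs = _center(X)
        fit.variant_ids_ = [f"v{j}" for j in range(alpha.shape[1])]
        fit.positions_ = np.arange(alpha.shape[1])
        return fit

    def test_dominant_variant_singleton_set(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(100, 3))
        fit = self._fit_with_alpha(np.array([[0.97, 0.02, 0.01]]), X)
        sets = extract_credible_sets(fit, coverage=0.95)
        assert len(sets) == 1 and sets[0].variant_indices == [0]
        assert sets[0].purity_min == 1.0

    def test_near_tie_two_member_set(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=(200, 1))
        X = np.hstack([x, x + rng.normal(size=(200, 1)) * 0.05, rng.normal(size=(200, 1))])
        fit = self._fit_with_alpha(np.array([[0.57, 0.43, 1e-9]]), X)
        sets = extract_credible_sets(fit, coverage=0.95)
        assert len(sets) == 1
        assert sets[0].variant_indices == [0, 1]
        assert sets[0].coverage >= 0.95

    def test_minimality_dropping_smallest_breaks_coverage(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=(300, 1))
        X = x + rng.normal(size=(300, 4)) * 0.05
        fit = self._fit_with_alpha(np.array([[0.4, 0.3, 0.27, 0.03]]), X)
        (cs,) = extract_credible_sets(fit, coverage=0.95)
        mass = sum(cs.alpha)
        assert mass >= 0.95
        assert mass - min(cs.alpha) < 0.95

    def test_low_purity_set_discarded(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(500, 2))  # independent columns, |r| ~ 0
        fit = self._fit_with_alpha(np.array([[0.5, 0.5]]), X)
        assert extract_credible_sets(fit, coverage=0.95, min_purity=0.5) == []

    def test_invalid_coverage_rejected(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(50, 2))
        fit = self._fit_with_alpha(np.array([[0.6, 0.4]]), X)
        with pytest.raises(ValueError):
            extract_credible_sets(fit, coverage=1.5)


class TestResidualize:
    def test_intercept_only_centers(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        assert np.allclose(residualize_covariates(y, None), y - y.mean())

    def test_exact_linear_dependence_gives_zero(self):
        rng = np.random.default_rng(21)
        C = rng.normal(size=(50, 3))
        y = C @ np.array([1.0, -2.0, 0.5]) + 4.0
        assert np.abs(residualize_covariates(y, C)).max() < 1e-10

    def test_orthogonality(self):
        rng = np.random.default_rng(22)
        C = rng.normal(size=(100, 4))
        y = rng.normal(size=100)
        r = residualize_covariates(y, C)
        assert np.abs(C.T @ r).max() < 1e-8

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(23)
        c = rng.normal(size=(30, 1))
        C = np.hstack([c, 2 * c])
        with pytest.raises(ValueError, match="pc_dup"):
            residualize_covariates(rng.normal(size=30), C, names=["pc1", "pc_dup"])


def test_mean_impute_fills_column_means():
    X = np.array([[1.0, np.nan], [3.0, 4.0], [np.nan, 6.0]])
    out = mean_impute(X)
    assert out[2, 0] == pytest.approx(2.0)
    assert out[0, 1] == pytest.approx(5.0)
    assert np.isfinite(out).all()
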