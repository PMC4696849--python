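"""Penalized Poisson mean model: fitter correctness and path semantics."""

import numpy as np
import pytest
import statsmodels.api as sm

from fallforecast import lasso


def _poisson_fixture(n=50, p=2, seed=0, base=0.6):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = 0.4 * (-1.0) ** np.arange(p)
    y = rng.poisson(np.exp(np.log(base) + X @ beta))
    return X, y


def _objective(X, y, intercept, beta, lam):
    Xs, _, _ = lasso._standardize(X)
    eta = intercept + Xs @ beta
    return float(np.mean(np.exp(eta) - y * eta) + lam * np.abs(beta).sum())


class TestFitter:
    def test_unpenalized_matches_glm_oracle(self):
        """lambda=0 agrees with an independent Newton solver (statsmodels GLM)."""
        X, y = _poisson_fixture(n=50, p=2, seed=1)
        fit = lasso.fit_poisson_lasso(X, y, lambda_=0.0)
        Xs, _, _ = lasso._standardize(X)
        oracle = sm.GLM(y, sm.add_constant(Xs), family=sm.families.Poisson()).fit()
        got = np.r_[fit.intercept, fit.coefficients]
        assert np.abs(got - oracle.params).max() < 1e-4

    def test_lambda_max_gives_null_model(self):
        X, y = _poisson_fixture(n=80, p=5, seed=2)
        lmax = lasso.lambda_max(X, y)
        fit = lasso.fit_poisson_lasso(X, y, lambda_=lmax * 1.5)
        assert fit.n_active == 0
        assert fit.intercept == pytest.approx(np.log(y.mean()), abs=1e-12)

    def test_matches_statsmodels_regularized_at_one_lambda(self):
        """Independent penalized cross-check (statsmodels elastic net, L1_wt=1)."""
        X, y = _poisson_fixture(n=120, p=6, seed=3)
        lam = 0.03
        fit = lasso.fit_poisson_lasso(X, y, lambda_=lam)
        Xs, _, _ = lasso._standardize(X)
        alpha = np.r_[0.0, np.full(6, lam)]  # intercept unpenalized
        oracle = sm.GLM(y, sm.add_constant(Xs), family=sm.families.Poisson()).fit_regularized(
            alpha=alpha, L1_wt=1.0, cnvrg_tol=1e-10, maxiter=2000
        )
        assert np.abs(np.r_[fit.intercept, fit.coefficients] - oracle.params).max() < 1e-3

    def test_solution_beats_random_perturbations(self):
        """Penalized objective at the solution is a local (coordinate) optimum."""
        rng = np.random.default_rng(4)
        for seed in range(3):
            X, y = _poisson_fixture(n=100, p=5, seed=seed)
            lam = 0.5 * lasso.lambda_max(X, y) * 0.2
            fit = lasso.fit_poisson_lasso(X, y, lambda_=lam)
            base = _objective(X, y, fit.intercept, fit.coefficients, lam)
            for _ in range(1000):
                eps = rng.normal(0, 0.01, size=5)
                perturbed = _objective(X, y, fit.intercept, fit.coefficients + eps, lam)
                assert perturbed >= base - 1e-9

    def test_all_zero_outcome_clamped_with_warning(self):
        X = np.random.default_rng(5).standard_normal((30, 3))
        y = np.zeros(30)
        with pytest.warns(UserWarning, match="clamped"):
            fit = lasso.fit_poisson_lasso(X, y, lambda_=0.1)
        assert fit.intercept >= np.log(1e-8) - 1e-12

    def test_input_validation(self):
        X, y = _poisson_fixture()
        with pytest.raises(ValueError, match="missing"):
            Xn = X.copy()
            Xn[0, 0] = np.nan
            lasso.fit_poisson_lasso_path(Xn, y)
        with pytest.raises(ValueError):
            lasso.fit_poisson_lasso_path(X, y - 0.5)

    def test_constant_column_gets_zero_coefficient(self):
        X, y = _poisson_fixture(n=60, p=3, seed=6)
        X[:, 1] = 7.0
        fit = lasso.fit_poisson_lasso(X, y, lambda_=1e-4)
        assert fit.coefficients[1] == 0.0


class TestPath:
    def test_truncation_rule_on_fabricated_path(self):
        """Cap=3 on active sizes {0,1,2,4,7} selects the size-2 solution."""
        sizes = [0, 1, 2, 4, 7]
        coefs = np.zeros((5, 8))
        for i, s in enumerate(sizes):
            coefs[i, :s] = 1.0
        path = lasso.PoissonLassoPath(
            lambdas=np.geomspace(1, 0.01, 5),
            intercepts=np.zeros(5),
            coefficients=coefs,
            feature_names=[f"x{j}" for j in range(8)],
            standardization=(np.zeros(8), np.ones(8)),
        )
        idx = path.truncation_index(3)
        assert path.n_active[idx] == 2

    def test_constrained_fit_respects_cap(self):
        X, y = _poisson_fixture(n=150, p=12, seed=7)
        for cap in (1, 3, 6):
            fit = lasso.fit_poisson_lasso(X, y, max_active=cap)
            assert fit.n_active <= cap

    def test_active_size_nondecreasing_on_fixture(self):
        X, y = _poisson_fixture(n=200, p=8, seed=8)
        path = lasso.fit_poisson_lasso_path(X, y)
        assert np.all(np.diff(path.n_active) >= 0)

    def test_parameter_recovery_on_strong_signal(self):
        """Active set captures >=4 of 5 strong true covariates in >=80% of seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((1500, 30))
            beta = np.zeros(30)
            beta[:5] = 0.4 * (-1.0) ** np.arange(5)
            y = rng.poisson(np.exp(np.log(0.5) + X @ beta))
            fit = lasso.fit_poisson_lasso(X, y, max_active=10)
            active_idx = set(np.flatnonzero(fit.coefficients))
            hits += len(active_idx & set(range(5))) >= 4
        assert hits >= 16


class TestPredict:
    def test_null_fit_predicts_constant_rate(self):
        X, y = _poisson_fixture(n=40, p=3, seed=9)
        fit = lasso.LassoFit(
            intercept=float(np.log(0.42)),
            coefficients=np.zeros(3),
            feature_names=["a", "b", "c"],
            lambda_=1.0,
            standardization=(np.zeros(3), np.ones(3)),
        )
        assert np.allclose(lasso.predict_mu(fit, X), 0.42)

    def test_log_linearity_in_standardized_units(self):
        fit = lasso.LassoFit(
            intercept=0.0,
            coefficients=np.array([0.3]),
            feature_names=["a"],
            lambda_=0.0,
            standardization=(np.array([0.0]), np.array([2.0])),
        )
        mu1 = lasso.predict_mu(fit, np.array([[2.0]]))
        mu2 = lasso.predict_mu(fit, np.array([[4.0]]))
        assert mu2[0] / mu1[0] == pytest.approx(np.exp(0.3 * 1.0))  # +1 std unit

    def test_column_mismatch_names_columns(self):
        X, y = _poisson_fixture(n=30, p=2, seed=10)
        fit = lasso.fit_poisson_lasso(X, y, lambda_=0.05, feature_names=["aa", "bb"])
        with pytest.raises(ValueError, match="aa"):
            lasso.predict_mu(fit, np.ones((4, 3)))

    def test_training_means_reproduced(self):
        """Predicting on the training design reproduces the fitter's own means."""
        X, y = _poisson_fixture(n=80, p=4, seed=11)
        fit = lasso.fit_poisson_lasso(X, y, lambda_=0.0)
        Xs, _, _ = lasso._standardize(X)
        eta = fit.intercept + Xs @ fit.coefficients
        assert np.allclose(lasso.predict_mu(fit, X), np.exp(eta), rtol=1e-10)

    def test_json_round_trip(self):
        X, y = _poisson_fixture(n=60, p=3, seed=12)
        fit = lasso.fit_poisson_lasso(X, y, max_active=2)
        back = lasso.LassoFit.from_json(fit.to_json())
        assert back.active_set == fit.active_set
        assert np.allclose(back.coefficients, fit.coefficients)
        assert back.intercept == pytest.approx(fit.intercept)
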