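"""Sparse empirical Bayes regression: selection, shrinkage, inference,
cross-validation, and the PVE formulas."""

import numpy as np
import pytest

from dendroqtl.eblasso import (DEFAULT_HYPER_GRID, EBLasso,
                               cv_prediction_accuracy, cv_select_hyperparams,
                               pve_all, pve_per_marker, shrinkage_strength)


def gibbs_bayesian_lasso(y, X, n_iter=4000, burn=1000, lam2=1.0, seed=0):
    """Small Gibbs sampler for the Bayesian lasso (test-suite oracle only).

    Standard data augmentation: beta | tau ~ N, 1/tau_j^2 ~ inverse-Gaussian,
    sigma2 ~ scaled inverse chi-square.  Returns posterior mean of beta.
    Used to cross-check the empirical Bayes point estimates on small,
    strong-signal problems where both should land near the same place.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    XtX = Xc.T @ Xc
    Xty = Xc.T @ yc
    beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
    sigma2 = max(float(np.var(yc - Xc @ beta)), 1e-6)
    inv_tau2 = np.ones(p)
    draws = np.zeros(p)
    kept = 0
    for it in range(n_iter):
        A = XtX + np.diag(inv_tau2)
        A_inv = np.linalg.inv(A)
        mean = A_inv @ Xty
        beta = rng.multivariate_normal(mean, sigma2 * A_inv)
        resid = yc - Xc @ beta
        shape = (n - 1 + p) / 2.0
        scale = (resid @ resid + float(beta @ (inv_tau2 * beta))) / 2.0
        sigma2 = scale / rng.gamma(shape, 1.0)
        mu_ig = np.sqrt(lam2 * sigma2 / np.maximum(beta**2, 1e-12))
        # inverse-Gaussian draws via transformation method
        nu = rng.standard_normal(p) ** 2
        x = mu_ig + (mu_ig**2 * nu) / (2 * lam2) - (
            mu_ig / (2 * lam2)
        ) * np.sqrt(4 * mu_ig * lam2 * nu + mu_ig**2 * nu**2)
        z = rng.random(p)
        inv_tau2 = np.where(z <= mu_ig / (mu_ig + x), x, mu_ig**2 / np.maximum(x, 1e-12))
        inv_tau2 = np.clip(inv_tau2, 1e-8, 1e8)
        if it >= burn:
            draws += beta
            kept += 1
    return draws / kept


class TestFitBasics:
    def test_constant_phenotype(self):
        X = np.eye(12)
        res = EBLasso(np.zeros(12), X).fit()
        assert res.mu == 0.0
        assert np.all(res.beta == 0) and res.active.size == 0

    def test_rejects_bad_inputs(self):
        X = np.ones((12, 2))
        with pytest.raises(ValueError):
            EBLasso(np.full(12, np.nan), X)
        with pytest.raises(ValueError):
            EBLasso(np.zeros(5), np.ones((5, 1)))  # too few observations
        with pytest.raises(ValueError):
            EBLasso(np.zeros(12), X, b=0.0)

    def test_single_causal_recovered(self, rng):
        X = rng.integers(0, 2, (200, 50)).astype(float)
        y = 1.0 * X[:, 7] + rng.normal(0, 0.5, 200)
        res = EBLasso(y, X).fit()
        assert 7 in res.active
        assert res.beta[7] > 0
        k = np.flatnonzero(res.active == 7)[0]
        assert res.pvalues[k] < 1e-4

    def test_nonzero_iff_active(self, rng):
        X = rng.integers(0, 2, (100, 80)).astype(float)
        y = X[:, 3] - X[:, 60] + rng.normal(0, 0.5, 100)
        res = EBLasso(y, X).fit()
        nz = np.flatnonzero(res.beta != 0)
        np.testing.assert_array_equal(nz, res.active)

    def test_duplicated_causal_columns_collapse(self, rng):
        X = rng.integers(0, 2, (150, 30)).astype(float)
        X[:, 11] = X[:, 10]
        y = 1.0 * X[:, 10] + rng.normal(0, 0.4, 150)
        res = EBLasso(y, X).fit()
        assert len({10, 11} & set(res.active.tolist())) <= 1

    def test_summary_mentions_retained(self, rng):
        X = rng.integers(0, 2, (100, 20)).astype(float)
        y = 1.5 * X[:, 4] + rng.normal(0, 0.4, 100)
        text = EBLasso(y, X).fit().summary()
        assert "x4" in text and "retained" in text


class TestSelectionBehaviour:
    def test_null_data_retains_little(self):
        """On featureless data the greedy should keep the model (nearly)
        empty and call nothing significant."""
        reps_with_sig = 0
        for rep in range(20):
            rg = np.random.default_rng(200 + rep)
            X = rg.integers(0, 2, (150, 120)).astype(float)
            y = rg.normal(0, 1, 150)
            res = EBLasso(y, X).fit()
            reps_with_sig += res.significant(0.01).size > 0
        assert reps_with_sig <= 2

    def test_shrinkage_monotone_along_ladder(self, rng):
        """Walking the default ladder from weakest to strongest shrinkage
        never grows the retained set on a fixed dataset."""
        X = rng.integers(0, 2, (150, 100)).astype(float)
        y = X[:, 5] - 0.6 * X[:, 50] + rng.normal(0, 0.7, 150)
        grid = sorted(DEFAULT_HYPER_GRID, key=lambda ab: shrinkage_strength(*ab))
        sizes = [EBLasso(y, X, a=a, b=b).fit().active.size for a, b in grid]
        assert all(later <= earlier for earlier, later in zip(sizes, sizes[1:]))

    def test_weak_prior_approaches_ols(self, rng):
        """With the penalty effectively off (a = -1 makes the NEG penalty
        vanish) and strong signal, retained effects match OLS closely."""
        X = rng.integers(0, 2, (200, 5)).astype(float)
        beta_true = np.array([1.0, -0.8, 0.6, 0.9, -1.2])
        y = X @ beta_true + rng.normal(0, 1e-3, 200)
        res = EBLasso(y, X, a=-1.0, b=1.0).fit()
        assert res.active.size == 5
        Xd = np.column_stack([np.ones(200), X])
        ols = np.linalg.lstsq(Xd, y, rcond=None)[0][1:]
        np.testing.assert_allclose(res.beta, ols, atol=1e-3)

    def test_matches_gibbs_bayesian_lasso_oracle(self, rng):
        """On a small strong-signal problem the EB point estimates agree in
        sign and roughly in size with a full Bayesian lasso posterior mean."""
        X = rng.integers(0, 2, (120, 8)).astype(float)
        y = 1.2 * X[:, 2] - 1.0 * X[:, 5] + rng.normal(0, 0.4, 120)
        eb = EBLasso(y, X).fit()
        gibbs = gibbs_bayesian_lasso(y, X, seed=1)
        assert {2, 5} <= set(eb.active.tolist())
        for j in (2, 5):
            assert np.sign(eb.beta[j]) == np.sign(gibbs[j])
            assert abs(eb.beta[j] - gibbs[j]) < 0.35


class TestCV:
    def test_single_point_grid(self, rng):
        X = rng.integers(0, 2, (60, 10)).astype(float)
        y = rng.normal(0, 1, 60)
        assert cv_select_hyperparams(X, y, grid=[(0.5, 0.2)], seed=0) == (0.5, 0.2)

    def test_k_exceeding_n_rejected(self, rng):
        X = rng.integers(0, 2, (12, 4)).astype(float)
        with pytest.raises(ValueError):
            cv_select_hyperparams(X, rng.normal(size=12), k=13, seed=0)

    def test_null_selects_strong_shrinkage(self):
        strong_half = sorted(DEFAULT_HYPER_GRID,
                             key=lambda ab: -shrinkage_strength(*ab))[:3]
        hits = 0
        for rep in range(20):
            rg = np.random.default_rng(400 + rep)
            X = rg.integers(0, 2, (100, 60)).astype(float)
            y = rg.normal(0, 1, 100)
            ab = cv_select_hyperparams(X, y, seed=rep)
            hits += ab in strong_half
        assert hits >= 16

    def test_strong_signal_keeps_causal_after_cv(self, rng):
        X = rng.integers(0, 2, (150, 60)).astype(float)
        y = 1.5 * X[:, 20] + rng.normal(0, 0.5, 150)
        a, b = cv_select_hyperparams(X, y, seed=3)
        res = EBLasso(y, X, a=a, b=b).fit()
        assert 20 in res.active

    def test_fold_split_deterministic(self, rng):
        X = rng.integers(0, 2, (80, 30)).astype(float)
        y = X[:, 2] + rng.normal(0, 1, 80)
        assert (cv_select_hyperparams(X, y, seed=11)
                == cv_select_hyperparams(X, y, seed=11))


class TestPVE:
    def test_per_marker_formula(self):
        x = np.array([0.0, 1.0] * 10)
        y = np.concatenate([np.zeros(10), np.ones(10)])
        # var(x) = 0.25, var(y) = 0.25 -> beta=1 gives 100%
        assert np.isclose(pve_per_marker(1.0, x, y), 100.0)
        assert pve_per_marker(0.0, x, y) == 0.0
        y_half = x * np.sqrt(2.0)          # var(y) = 0.5, var(x) = 0.25
        assert np.isclose(pve_per_marker(1.0, x, y_half), 50.0)

    def test_pve_all_equals_r_squared(self, rng):
        for _ in range(50):
            n, k = 60, 4
            X = rng.standard_normal((n, k))
            y = X @ rng.standard_normal(k) + rng.standard_normal(n)
            design = np.column_stack([np.ones(n), X])
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            ss_res = float(np.sum((y - design @ coef) ** 2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 100.0 * (1.0 - ss_res / ss_tot)
            assert abs(pve_all(X, y) - r2) < 1e-10

    def test_pve_all_trivial_cases(self, rng):
        X = rng.integers(0, 2, (40, 3)).astype(float)
        y = X @ np.array([1.0, -2.0, 0.5]) + 3.0
        assert np.isclose(pve_all(X, y), 100.0, atol=1e-8)
        assert pve_all(np.empty((40, 0)), y) == 0.0


class TestCVAccuracy:
    def test_noiseless_linear(self, rng):
        X = rng.integers(0, 2, (100, 3)).astype(float)
        y = X @ np.array([1.0, 0.5, -0.7])
        assert cv_prediction_accuracy(X, y, seed=0) >= 0.999

    def test_null_accuracy_near_zero(self):
        rs = []
        for rep in range(100):
            rg = np.random.default_rng(3000 + rep)
            X = rg.integers(0, 2, (100, 10)).astype(float)
            y = rg.normal(0, 1, 100)
            rs.append(cv_prediction_accuracy(X, y, seed=rep))
        assert abs(np.nanmean(rs)) < 0.1
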