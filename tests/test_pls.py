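"""NIPALS PLS1: OLS equivalence, invariants, VIP, coefficient back-transforms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spipls import PLSRegressionNIPALS, fit_pls, r2_rmse, vip_scores
from spipls.pls import _coefficient_path

from conftest import random_regression


def _scaled(X, y):
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)
    return Xs, ys


class TestFit:
    def test_single_predictor_exact_fit(self):
        x = np.linspace(-2, 3, 9)
        y = -1.7 * x
        Xs, ys = _scaled(x[:, None], y)
        m = fit_pls(Xs, ys, 1)
        assert m.n_components_ == 1
        assert r2_rmse(ys, m.predict(Xs)).r2 == pytest.approx(1.0, abs=1e-12)
        assert m.coef_scaled(1)[0] == pytest.approx(-1.0)  # correlation sign

    @pytest.mark.parametrize("seed", range(6))
    def test_full_rank_equals_ols(self, seed):
        X, y = random_regression(seed, n=12, p=4)
        Xs, ys = _scaled(X, y)
        m = fit_pls(Xs, ys, 4)
        b_ols = np.linalg.lstsq(Xs, ys, rcond=None)[0]
        np.testing.assert_allclose(m.coef_scaled(4), b_ols, atol=1e-8)
        np.testing.assert_allclose(m.predict(Xs), Xs @ b_ols, atol=1e-8)

    def test_orthogonal_response_early_stop(self):
        """y orthogonal to every column of X: zero components, mean prediction."""
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.standard_normal((10, 5)))
        Xs = Q[:, :3]
        ys = Q[:, 4]  # exactly orthogonal to the X columns
        m = fit_pls(Xs, ys, 2)
        assert m.n_components_ == 0
        np.testing.assert_allclose(m.predict(Xs), 0.0, atol=1e-12)

    def test_invariants_on_random_fits(self):
        for seed in range(5):
            X, y = random_regression(seed + 50, n=25, p=8, noise=0.5)
            m = PLSRegressionNIPALS(n_components=6, scale=True).fit(X, y)
            W, T = m.x_weights_, m.x_scores_
            np.testing.assert_allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-10)
            G = T.T @ T
            off = np.abs(G - np.diag(np.diag(G))).max()
            assert off < 1e-8 * np.trace(G)
            rmse_path = [r2_rmse(y, m.predict(X, a)).rmse
                         for a in range(1, m.n_components_ + 1)]
            assert all(b <= a + 1e-10 for a, b in zip(rmse_path, rmse_path[1:]))

    def test_bad_inputs(self):
        X = np.random.default_rng(0).standard_normal((8, 3))
        with pytest.raises(ValueError):
            PLSRegressionNIPALS(n_components=0).fit(X, X[:, 0])
        with pytest.raises(ValueError):
            PLSRegressionNIPALS(n_components=8).fit(X, X[:, 0])
        with pytest.raises(ValueError):
            fit_pls(X, np.zeros(8), 1)

    def test_sklearn_cross_check(self):
        """Independent oracle: sklearn's PLSRegression yields the same predictions."""
        from sklearn.cross_decomposition import PLSRegression

        for seed in (0, 1):
            X, y = random_regression(seed, n=30, p=7, noise=0.4)
            for A in (1, 3, 5):
                ours = PLSRegressionNIPALS(A, scale=True).fit(X, y)
                theirs = PLSRegression(n_components=A, scale=True).fit(X, y)
                np.testing.assert_allclose(ours.predict(X),
                                           theirs.predict(X).ravel(), atol=1e-6)


class TestPredictAndRawCoefficients:
    def test_training_prediction_matches_ols_at_full_rank(self):
        X, y = random_regression(11, n=15, p=5)
        m = PLSRegressionNIPALS(5, scale=True).fit(X, y)
        Z = np.column_stack([np.ones(15), X])
        coef = np.linalg.lstsq(Z, y, rcond=None)[0]
        np.testing.assert_allclose(m.predict(X), Z @ coef, atol=1e-8)

    def test_raw_and_scaled_paths_agree(self):
        X, y = random_regression(12, n=40, p=6, noise=0.5)
        m = PLSRegressionNIPALS(4, scale=True).fit(X, y)
        rng = np.random.default_rng(5)
        X_new = rng.standard_normal((100, 6)) * 3.0 + 1.0
        for A in (1, 2, 4):
            intercept, b_raw = m.raw_coefficients(A)
            np.testing.assert_allclose(m.predict(X_new, A),
                                       intercept + X_new @ b_raw, atol=1e-8)

    def test_identity_scaling_gives_raw_equals_scaled(self):
        X, y = random_regression(13, n=20, p=4)
        Xs, ys = _scaled(X, y)
        m = fit_pls(Xs, ys, 3)
        intercept, b_raw = m.raw_coefficients(3)
        np.testing.assert_allclose(b_raw, m.coef_scaled(3), atol=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_intercept_translation_equivariance(self):
        X, y = random_regression(14, n=30, p=5, noise=0.3)
        m1 = PLSRegressionNIPALS(3, scale=True).fit(X, y)
        m2 = PLSRegressionNIPALS(3, scale=True).fit(X, y + 10.0)
        i1, b1 = m1.raw_coefficients(3)
        i2, b2 = m2.raw_coefficients(3)
        np.testing.assert_allclose(b2, b1, atol=1e-10)
        assert i2 - i1 == pytest.approx(10.0, abs=1e-10)

    def test_column_permutation_equivariance(self):
        X, y = random_regression(15, n=30, p=6, noise=0.4)
        perm = np.array([3, 0, 5, 1, 4, 2])
        m1 = PLSRegressionNIPALS(3, scale=True).fit(X, y)
        m2 = PLSRegressionNIPALS(3, scale=True).fit(X[:, perm], y)
        np.testing.assert_allclose(m2.coef_scaled(3), m1.coef_scaled(3)[perm],
                                   atol=1e-10)
        np.testing.assert_allclose(m2.vip(3), m1.vip(3)[perm], atol=1e-10)


class TestVIP:
    def test_single_predictor_vip_is_one(self):
        x = np.linspace(-1, 1, 7)
        m = fit_pls(x[:, None], 0.5 * x, 1)
        np.testing.assert_allclose(m.vip(1), [1.0], atol=1e-12)

    def test_two_orthogonal_predictors_all_weight_on_one(self):
        rng = np.random.default_rng(8)
        Q, _ = np.linalg.qr(rng.standard_normal((12, 2)))
        Xs = Q * np.sqrt(11)  # unit-variance orthogonal columns
        ys = Xs[:, 0].copy()
        m = fit_pls(Xs, ys, 1)
        np.testing.assert_allclose(m.vip(1), [np.sqrt(2.0), 0.0], atol=1e-10)

    def test_formula_oracle(self):
        """Direct evaluation of the VIP formula from W, q, T assembled
        independently of the fitting path."""
        X, y = random_regression(16, n=20, p=6, noise=0.5)
        m = PLSRegressionNIPALS(3, scale=True).fit(X, y)
        W, T, q = m.x_weights_, m.x_scores_, m.y_loadings_
        ssy = np.array([q[a] ** 2 * (T[:, a] @ T[:, a]) for a in range(3)])
        expected = np.sqrt(6 * (W[:, :3] ** 2 @ ssy) / ssy.sum())
        np.testing.assert_allclose(vip_scores(m, 3), expected, atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(8, 30), p=st.integers(2, 8),
           a=st.integers(1, 4))
    def test_mean_square_is_one(self, seed, n, p, a):
        X, y = random_regression(seed, n=n, p=p, noise=1.0)
        a = min(a, n - 1, p)
        m = PLSRegressionNIPALS(a, scale=True).fit(X, y)
        if m.n_components_ >= 1:
            assert np.mean(m.vip() ** 2) == pytest.approx(1.0, abs=1e-10)


class TestMetrics:
    def test_perfect_and_mean_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert r2_rmse(y, y).r2 == 1.0
        assert r2_rmse(y, y).rmse == 0.0
        assert r2_rmse(y, np.full(4, y.mean())).r2 == pytest.approx(0.0)

    def test_hand_worked_case(self):
        m = r2_rmse([1, 2, 3, 4], [1, 2, 3, 6])
        assert m.rmse == pytest.approx(1.0)
        assert m.r2 == pytest.approx(1 - 4 / 5)

    def test_constant_truth_rejected(self):
        with pytest.raises(ValueError):
            r2_rmse([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


def test_coefficient_path_consistency():
    """The coefficient path at a ≤ A equals a fresh fit with a components."""
    X, y = random_regression(17, n=30, p=8, noise=0.5)
    Xs, ys = _scaled(X, y)
    m = fit_pls(Xs, ys, 5)
    for a in range(1, 6):
        m_a = fit_pls(Xs, ys, a)
        np.testing.assert_allclose(m.coef_scaled(a), m_a.coef_scaled(a), atol=1e-10)
    B = _coefficient_path(m.x_weights_, m.x_loadings_, m.y_loadings_)
    np.testing.assert_allclose(B, m.coef_path_, atol=1e-12)
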