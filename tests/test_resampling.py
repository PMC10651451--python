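"""Cross-validation, jack-knife significance, and the permutation test."""

import numpy as np
import pytest
from scipy import stats as st

from spipls import (CVResult, RandTestResult, fit_pls, jackknife_significance,
                    randomization_test, repeated_kfold_cv, select_ncomp)
from spipls.dataset_io import fit_scaler

from conftest import random_regression


class TestRepeatedKFoldCV:
    def test_noiseless_single_predictor(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(40)
        cv = repeated_kfold_cv(x[:, None], 2.0 + 3.0 * x, 1, k=5, reps=3, seed=1)
        assert cv.rmsecv[0] < 1e-10
        assert cv.r2cv[0] > 1.0 - 1e-10

    def test_each_sample_held_out_once_per_rep(self):
        X, y = random_regression(1, n=30, p=5, noise=0.5)
        cv = repeated_kfold_cv(X, y, 3, k=8, reps=4, seed=2)
        assert cv.predictions.shape == (4, 30, 3)
        assert np.all(np.isfinite(cv.predictions))  # every slot filled exactly once

    def test_loo_matches_brute_force(self):
        """reps=1, k=n leave-one-out equals an explicit per-sample refit loop."""
        X, y = random_regression(4, n=10, p=2, noise=0.3)
        cv = repeated_kfold_cv(X, y, 2, k=10, reps=1, seed=0)
        expected = np.zeros((10, 2))
        for i in range(10):
            tr = np.delete(np.arange(10), i)
            sc = fit_scaler((X[tr], y[tr]))
            m = fit_pls(sc.transform(X[tr]), sc.transform_y(y[tr]), 2)
            for a in (1, 2):
                pred = sc.transform(X[[i]]) @ m.coef_scaled(a)
                expected[i, a - 1] = sc.inverse_transform_y(pred)[0]
        np.testing.assert_allclose(cv.predictions[0], expected, atol=1e-10)

    def test_null_data_r2cv_nonpositive(self):
        """CV R^2 of pure noise is non-positive in expectation, per component."""
        neg = np.zeros(5)
        runs = 50
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            X = rng.standard_normal((60, 20))
            y = rng.standard_normal(60)
            cv = repeated_kfold_cv(X, y, 5, k=8, reps=2, seed=seed)
            neg += cv.r2cv <= 0
        assert np.all(neg >= 0.9 * runs)

    def test_determinism_and_fold_errors(self):
        X, y = random_regression(5, n=24, p=4, noise=0.5)
        cv1 = repeated_kfold_cv(X, y, 3, k=6, reps=2, seed=9)
        cv2 = repeated_kfold_cv(X, y, 3, k=6, reps=2, seed=9)
        np.testing.assert_array_equal(cv1.predictions, cv2.predictions)
        with pytest.raises(ValueError):
            repeated_kfold_cv(X, y, 3, k=1)
        with pytest.raises(ValueError):
            repeated_kfold_cv(X, y, 3, k=25)


class TestJackknife:
    def _cv_with_segments(self, seg_values, b_full, k, reps=1):
        p = 1
        seg = np.array(seg_values, dtype=float).reshape(reps, k, p, 1)
        n = 2 * k
        return CVResult(k=k, reps=reps, a_max=1, y=np.arange(n, dtype=float),
                        predictions=np.zeros((reps, n, 1)), segment_coefs=seg,
                        rmsecv=np.zeros(1), r2cv=np.zeros(1))

    def test_hand_worked_four_segments(self):
        """k=4, segments (1.9, 2.1, 2.0, 2.0) around b=2: s^2 = 0.015,
        t = 16.33, df = 3, p < 0.001."""
        cv = self._cv_with_segments([1.9, 2.1, 2.0, 2.0], 2.0, k=4)
        res = jackknife_significance(cv, [2.0], 1)
        assert res.se[0] ** 2 == pytest.approx(0.015)
        assert res.t[0] == pytest.approx(2.0 / np.sqrt(0.015), rel=1e-12)
        assert res.t[0] == pytest.approx(16.33, abs=0.01)
        assert res.df == 3
        assert res.p_value[0] < 0.001
        assert res.ci_low[0] < 2.0 < res.ci_high[0]

    def test_degenerate_zero_spread(self):
        cv = self._cv_with_segments([1.5, 1.5, 1.5, 1.5], 1.5, k=4)
        res = jackknife_significance(cv, [1.5], 1)
        assert res.se[0] == 0.0 and res.p_value[0] == 0.0
        res0 = jackknife_significance(cv, [0.0], 1)
        # zero coefficient with zero spread relative to itself
        cv0 = self._cv_with_segments([0.0, 0.0, 0.0, 0.0], 0.0, k=4)
        res0 = jackknife_significance(cv0, [0.0], 1)
        assert res0.p_value[0] == 1.0

    def test_p_monotone_in_abs_t(self):
        cv = self._cv_with_segments([1.9, 2.1, 2.0, 2.0], 2.0, k=4)
        p_big = jackknife_significance(cv, [2.0], 1).p_value[0]
        p_small = jackknife_significance(cv, [0.05], 1).p_value[0]
        assert p_big < p_small

    def test_null_p_values_approximately_uniform(self):
        """Inert-variable p-values are close to U(0,1): KS distance < 0.15."""
        pvals = []
        for d in range(10):
            rng = np.random.default_rng(4000 + d)
            X = rng.standard_normal((60, 20))
            y = rng.standard_normal(60)
            cv = repeated_kfold_cv(X, y, 3, k=8, reps=10, seed=d)
            from spipls import PLSRegressionNIPALS
            model = PLSRegressionNIPALS(3, scale=True).fit(X, y)
            pvals.extend(jackknife_significance(cv, model.coef_scaled(2), 2).p_value)
        ks = st.kstest(np.array(pvals), "uniform").statistic
        assert len(pvals) == 200
        assert ks < 0.15

    def test_consistency_p_shrinks_with_n(self):
        """Jack-knife p of a truly active variable goes to 0 as n grows."""
        ps = []
        for n in (50, 200, 800):
            rng = np.random.default_rng(n)
            X = rng.standard_normal((n, 5))
            y = X[:, 0] * 0.5 + rng.standard_normal(n)
            cv = repeated_kfold_cv(X, y, 3, k=8, reps=5, seed=n)
            from spipls import PLSRegressionNIPALS
            m = PLSRegressionNIPALS(3, scale=True).fit(X, y)
            A = cv.best_ncomp()
            ps.append(jackknife_significance(cv, m.coef_scaled(A), A).p_value[0])
        assert ps[0] > ps[2]
        assert ps[2] < 1e-4


class TestRandomizationTest:
    def test_perfect_first_component_minimal_alpha(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        res = randomization_test(x[:, None], 2.0 * x, 1, nperm=199, seed=0)
        assert res.alpha[0] == pytest.approx(1.0 / 200.0)

    def test_alpha_never_zero_and_bounds(self):
        X, y = random_regression(6, n=30, p=5, noise=0.2)
        res = randomization_test(X, y, 3, nperm=99, seed=1)
        assert np.all(res.alpha > 0.0)
        assert np.all(res.alpha <= 1.0)

    def test_alpha_decreases_with_signal_strength(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((50, 8))
        noise = rng.standard_normal(50)
        alphas = []
        for strength in (0.0, 0.5, 2.0):
            y = strength * X[:, 0] + noise
            res = randomization_test(X, y, 1, nperm=199, seed=5)
            alphas.append(res.alpha[0])
        assert alphas[2] <= alphas[1] <= alphas[0] + 0.05

    def test_select_ncomp_contiguity(self):
        res = RandTestResult(c_obs=np.ones(4), null=np.zeros((99, 4)),
                             alpha=np.array([0.001, 0.02, 0.029, 0.31]))
        assert select_ncomp(res, alpha_crit=0.05) == 3
        res2 = RandTestResult(c_obs=np.ones(3), null=np.zeros((99, 3)),
                              alpha=np.array([0.2, 0.01, 0.01]))
        assert select_ncomp(res2, alpha_crit=0.05) == 0

    def test_input_validation(self):
        X, y = random_regression(8, n=20, p=4, noise=0.5)
        with pytest.raises(ValueError):
            randomization_test(X, y, 1, nperm=50)
        with pytest.raises(ValueError):
            randomization_test(X, np.full(20, 2.0), 1, nperm=99)
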