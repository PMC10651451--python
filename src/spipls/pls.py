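"""NIPALS PLS1 regression: fitting, coefficient paths, VIP scores, fit metrics.

The estimator follows the classical single-response NIPALS recursion.  With
autoscaled data ``X_1 = X``, ``y_1 = y``, component ``a`` extracts

    w_a = X_a' y_a / ||X_a' y_a||        (unit-norm weight)
    t_a = X_a w_a                        (X score)
    p_a = X_a' t_a / (t_a' t_a)          (X loading)
    q_a = y_a' t_a / (t_a' t_a)          (y loading)

followed by deflation ``X_{a+1} = X_a - t_a p_a'`` and ``y_{a+1} = y_a - q_a t_a``
(y-deflation is numerically immaterial for PLS1 but fixes the convention).
Scaled regression coefficients for any leading block of components are
``b = W (P'W)^{-1} q``; raw-unit coefficients back-transform through the
autoscaling statistics so a final model can be applied to unscaled assay values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .dataset_io import ScalingModel

__all__ = [
    "PLSRegressionNIPALS",
    "FitMetrics",
    "fit_pls",
    "predict",
    "raw_coefficients",
    "vip_scores",
    "r2_rmse",
]

#: deflation stops when the residual covariance ||X_a' y_a|| falls below this
DEFLATION_TOL = 1e-12


def _nipals_pls1(Xs: np.ndarray, ys: np.ndarray, n_components: int, tol: float):
    """Run the NIPALS recursion; returns (W, P, T, q) with achieved components."""
    n, p = Xs.shape
    Xa = Xs.copy()
    ya = ys.astype(float).copy()
    W, P, T, q = [], [], [], []
    for _ in range(n_components):
        cov = Xa.T @ ya
        norm = np.linalg.norm(cov)
        if norm < tol:
            break
        w = cov / norm
        t = Xa @ w
        tt = float(t @ t)
        if tt < tol:
            break
        p_a = (Xa.T @ t) / tt
        q_a = float(ya @ t) / tt
        Xa -= np.outer(t, p_a)
        ya = ya - q_a * t
        W.append(w)
        P.append(p_a)
        T.append(t)
        q.append(q_a)
    if W:
        return (np.column_stack(W), np.column_stack(P), np.column_stack(T),
                np.asarray(q, dtype=float))
    return (np.zeros((p, 0)), np.zeros((p, 0)), np.zeros((n, 0)), np.zeros(0))


def _coefficient_path(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Scaled coefficients b(A') for every A' = 1..A, as a (p, A) matrix."""
    p, A = W.shape
    B = np.zeros((p, A))
    R = P.T @ W  # upper triangular up to round-off; solved exactly per block
    for a in range(1, A + 1):
        B[:, a - 1] = W[:, :a] @ np.linalg.solve(R[:a, :a], q[:a])
    return B


class PLSRegressionNIPALS(RegressorMixin, BaseEstimator):
    """Single-response PLS regression via NIPALS with built-in autoscaling.

    Parameters
    ----------
    n_components : int
        Number of latent components requested; must satisfy
        ``1 <= n_components <= min(n - 1, p)``.  Fewer may be achieved when the
        residual X'y covariance vanishes (recorded in ``n_components_``).
    scale : bool
        If True (default) center and autoscale X and y with ddof=1 statistics
        estimated from the training data; if False the data are assumed
        already centered/scaled.

    Attributes
    ----------
    x_weights_ : (p, A) unit-norm weight matrix W.
    x_loadings_ : (p, A) loading matrix P.
    x_scores_ : (n, A) orthogonal score matrix T.
    y_loadings_ : (A,) y-loading vector q.
    coef_path_ : (p, A) scaled coefficients for each leading component count.
    n_components_ : achieved number of components.
    scaler_ : :class:`ScalingModel` with the training statistics.
    """

    def __init__(self, n_components: int = 2, scale: bool = True,
                 deflation_tol: float = DEFLATION_TOL):
        self.n_components = n_components
        self.scale = scale
        self.deflation_tol = deflation_tol

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be a 2-D array")
        n, p = X.shape
        if len(y) != n:
            raise ValueError("X and y length mismatch")
        if n < 2:
            raise ValueError("need at least 2 samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite values in input")
        if not 1 <= self.n_components <= min(n - 1, p):
            raise ValueError(
                f"n_components={self.n_components} out of range 1..{min(n - 1, p)}")
        if self.scale:
            sds = X.std(axis=0, ddof=1)
            if np.any(sds == 0.0):
                raise ValueError("constant predictor column; autoscaling undefined")
            y_sd = float(np.std(y, ddof=1))
            if y_sd == 0.0:
                raise ValueError("constant response")
            self.scaler_ = ScalingModel(means=X.mean(axis=0), sds=sds,
                                        y_mean=float(np.mean(y)), y_sd=y_sd)
        else:
            if np.allclose(y, 0.0):
                raise ValueError("all-zero response")
            self.scaler_ = ScalingModel(means=np.zeros(p), sds=np.ones(p),
                                        y_mean=0.0, y_sd=1.0)
        Xs = self.scaler_.transform(X)
        ys = self.scaler_.transform_y(y)
        W, P, T, q = _nipals_pls1(Xs, ys, self.n_components, self.deflation_tol)
        self.x_weights_ = W
        self.x_loadings_ = P
        self.x_scores_ = T
        self.y_loadings_ = q
        self.n_components_ = W.shape[1]
        self.coef_path_ = (_coefficient_path(W, P, q) if self.n_components_
                           else np.zeros((p, 0)))
        self.n_features_in_ = p
        return self

    # ------------------------------------------------------------------
    def _check_ncomp(self, n_components: int | None) -> int:
        if not hasattr(self, "x_weights_"):
            raise ValueError("model is not fitted")
        A = self.n_components_ if n_components is None else int(n_components)
        if A > self.n_components_ or A < 0:
            raise ValueError(f"n_components={A} exceeds achieved {self.n_components_}")
        return A

    def coef_scaled(self, n_components: int | None = None) -> np.ndarray:
        """Regression coefficients for autoscaled X and y at the given component count."""
        A = self._check_ncomp(n_components)
        if A == 0:
            return np.zeros(self.n_features_in_)
        return self.coef_path_[:, A - 1].copy()

    def raw_coefficients(self, n_components: int | None = None):
        """(intercept, b_raw): the model as a plain linear function of raw inputs."""
        b_s = self.coef_scaled(n_components)
        s = self.scaler_
        b_raw = b_s * (s.y_sd / s.sds)
        intercept = s.y_mean - float(b_raw @ s.means)
        return intercept, b_raw

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} columns, got shape {X.shape}")
        b_s = self.coef_scaled(n_components)
        ys = self.scaler_.transform(X) @ b_s
        return self.scaler_.inverse_transform_y(ys)

    def transform(self, X) -> np.ndarray:
        """Project new (raw) observations onto the latent components."""
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        # successive deflation of the new data against the fitted loadings
        scores = np.zeros((Xs.shape[0], self.n_components_))
        Xa = Xs.copy()
        for a in range(self.n_components_):
            t = Xa @ self.x_weights_[:, a]
            Xa -= np.outer(t, self.x_loadings_[:, a])
            scores[:, a] = t
        return scores

    def vip(self, n_components: int | None = None) -> np.ndarray:
        """Variable importance for projection over the first ``n_components`` components.

        VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ) with
        SSY_a = q_a^2 (t_a' t_a); the mean square of the VIP vector is 1.
        """
        A = self._check_ncomp(n_components)
        if A < 1:
            raise ValueError("VIP requires at least one component")
        p = self.n_features_in_
        ssy = self.y_loadings_[:A] ** 2 * np.einsum(
            "ij,ij->j", self.x_scores_[:, :A], self.x_scores_[:, :A])
        total = float(ssy.sum())
        if total <= 0.0:
            raise ValueError("no explained response variance; VIP undefined")
        return np.sqrt(p * (self.x_weights_[:, :A] ** 2 @ ssy) / total)


# ---------------------------------------------------------------------------
# Functional wrappers (thin layer over the estimator)
# ---------------------------------------------------------------------------


def fit_pls(X_scaled, y_scaled, n_components: int) -> PLSRegressionNIPALS:
    """Fit NIPALS PLS1 on already centered/scaled data."""
    return PLSRegressionNIPALS(n_components=n_components, scale=False).fit(
        X_scaled, y_scaled)


def predict(model: PLSRegressionNIPALS, X_new_raw, n_components: int | None = None):
    return model.predict(X_new_raw, n_components=n_components)


def raw_coefficients(model: PLSRegressionNIPALS, n_components: int | None = None):
    return model.raw_coefficients(n_components)


def vip_scores(model: PLSRegressionNIPALS, n_components: int | None = None):
    return model.vip(n_components)


@dataclass
class FitMetrics:
    """Coefficient of determination and root-mean-square error (units of y)."""

    r2: float
    rmse: float


def r2_rmse(y_true, y_pred) -> FitMetrics:
    """R^2 = 1 - SSres/SStot and RMSE = sqrt(mean squared error)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    if len(y_true) < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant y_true: R^2 undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return FitMetrics(r2=1.0 - ss_res / ss_tot,
                      rmse=float(np.sqrt(np.mean((y_true - y_pred) ** 2))))
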