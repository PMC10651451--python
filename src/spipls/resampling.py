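"""Repeated randomized k-fold CV, jack-knife coefficient significance, permutation test.

Cross-validation re-randomizes the fold assignment in every repetition and, by
default, refits the autoscaling inside each training segment so no held-out
statistics leak into calibration.  Held-out squared errors are pooled over all
repetitions when forming RMSEcv / R2cv per component count.

Jack-knife significance follows the Martens convention: the spread of the
cross-validation segment coefficients around the full-model coefficient gives
a variance estimate per variable; significance is judged on a Student t with
k - 1 degrees of freedom, with segment variances averaged over repetitions.

The permutation (randomized) test scores each latent component by the absolute
covariance |t_a' u_a| between its X-score and the residual response, rebuilds
that statistic under random permutations of y, and reports the exceedance
probability alpha with the +1/(N+1) correction so alpha is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import ScalingModel, fit_scaler
from .pls import PLSRegressionNIPALS, fit_pls

__all__ = [
    "CVResult",
    "JackknifeResult",
    "RandTestResult",
    "repeated_kfold_cv",
    "jackknife_significance",
    "randomization_test",
    "select_ncomp",
]


@dataclass
class CVResult:
    """Held-out predictions and segment coefficients from repeated k-fold CV.

    ``predictions[r, i, a]`` is the held-out prediction (raw y units) of sample
    ``i`` in repetition ``r`` with ``a + 1`` components; ``segment_coefs[r, m]``
    holds the (p, A_max) scaled coefficient path of fold ``m``'s training model.
    """

    k: int
    reps: int
    a_max: int
    y: np.ndarray
    predictions: np.ndarray
    segment_coefs: np.ndarray
    rmsecv: np.ndarray = field(default=None)
    r2cv: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.rmsecv is None:
            err = self.predictions - self.y[None, :, None]
            self.rmsecv = np.sqrt(np.mean(err**2, axis=(0, 1)))
            ss_tot = float(np.sum((self.y - self.y.mean()) ** 2)) * self.reps
            self.r2cv = 1.0 - np.sum(err**2, axis=(0, 1)) / ss_tot

    def best_ncomp(self) -> int:
        """Component count minimizing RMSEcv."""
        return int(np.argmin(self.rmsecv)) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_components": np.arange(1, self.a_max + 1),
            "rmsecv": self.rmsecv,
            "r2cv": self.r2cv,
        })


def repeated_kfold_cv(X, y, a_max: int, k: int = 8, reps: int = 10, seed: int = 0,
                      scale_in_cv: bool = True,
                      scaler: ScalingModel | None = None) -> CVResult:
    """Repeated randomized k-fold cross-validation of NIPALS PLS1.

    Parameters
    ----------
    X, y : raw (unscaled) training data.
    a_max : largest component count evaluated; silently capped at what the
        smallest training segment supports.
    k, reps : folds per repetition and number of repetitions.
    scale_in_cv : refit autoscaling inside each training segment (strict
        no-leakage, default); if False, scale once with statistics from the
        whole training set (``scaler`` or freshly fitted).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples {n}")
    rng = np.random.default_rng(seed)
    min_train = n - int(np.ceil(n / k))
    a_max = int(min(a_max, p, min_train - 1))
    if a_max < 1:
        raise ValueError("no admissible component count for this fold configuration")
    if not scale_in_cv and scaler is None:
        scaler = fit_scaler((X, y))

    predictions = np.empty((reps, n, a_max))
    segment_coefs = np.zeros((reps, k, p, a_max))
    for r in range(reps):
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        for m, te in enumerate(folds):
            tr = np.setdiff1d(order, te, assume_unique=True)
            seg_scaler = fit_scaler((X[tr], y[tr])) if scale_in_cv else scaler
            Xs_tr = seg_scaler.transform(X[tr])
            ys_tr = seg_scaler.transform_y(y[tr])
            model = fit_pls(Xs_tr, ys_tr, a_max)
            A_ach = model.n_components_
            B = np.zeros((p, a_max))
            if A_ach:
                B[:, :A_ach] = model.coef_path_
                if A_ach < a_max:  # degenerate deflation: freeze at last component
                    B[:, A_ach:] = model.coef_path_[:, [A_ach - 1]]
            segment_coefs[r, m] = B
            Xs_te = seg_scaler.transform(X[te])
            predictions[r, te, :] = seg_scaler.inverse_transform_y(Xs_te @ B)
    return CVResult(k=k, reps=reps, a_max=a_max, y=y,
                    predictions=predictions, segment_coefs=segment_coefs)


# ---------------------------------------------------------------------------
# Jack-knife significance of regression coefficients
# ---------------------------------------------------------------------------


@dataclass
class JackknifeResult:
    """Per-variable jack-knife SE, t statistic, p-value and confidence interval."""

    b: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df: int
    p_value: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def to_frame(self, names=None) -> pd.DataFrame:
        df = pd.DataFrame({
            "coef": self.b, "se": self.se, "t": self.t,
            "p_value": self.p_value, "ci_low": self.ci_low, "ci_high": self.ci_high,
        })
        if names is not None:
            df.insert(0, "variable", list(names))
        return df


def jackknife_significance(cv: CVResult, full_model_b, n_components: int,
                           alpha_level: float = 0.05) -> JackknifeResult:
    """Martens-style jack-knife from CV segment coefficients.

    Per repetition ``r``: ``s2_jr = ((k-1)/k) * sum_m (b_j - b_j^(m))^2``;
    the variance is the mean of ``s2_jr`` over repetitions; ``t_j = b_j / s_j``
    on ``k - 1`` degrees of freedom.  Degenerate zero spread yields p = 0 for a
    nonzero coefficient (maximally stable) and p = 1 otherwise.
    """
    A = int(n_components)
    if not 1 <= A <= cv.a_max:
        raise ValueError(f"n_components={A} not available in CVResult (a_max={cv.a_max})")
    b = np.asarray(full_model_b, dtype=float).ravel()
    seg = cv.segment_coefs[:, :, :, A - 1]  # (reps, k, p)
    dev2 = (b[None, None, :] - seg) ** 2
    s2_per_rep = (cv.k - 1) / cv.k * dev2.sum(axis=1)  # (reps, p)
    s2 = s2_per_rep.mean(axis=0)
    se = np.sqrt(s2)
    df = cv.k - 1
    nz = se > 0.0
    t = np.zeros_like(b)
    p = np.ones_like(b)
    t[nz] = b[nz] / se[nz]
    p[nz] = 2.0 * stats.t.sf(np.abs(t[nz]), df)
    t[~nz] = np.where(b[~nz] > 0.0, np.inf, np.where(b[~nz] < 0.0, -np.inf, 0.0))
    p[~nz] = np.where(b[~nz] != 0.0, 0.0, 1.0)
    tcrit = stats.t.ppf(1.0 - alpha_level / 2.0, df)
    return JackknifeResult(b=b, se=se, t=t, df=df, p_value=p,
                           ci_low=b - tcrit * se, ci_high=b + tcrit * se)


# ---------------------------------------------------------------------------
# Randomized (permutation) test for component significance
# ---------------------------------------------------------------------------


@dataclass
class RandTestResult:
    """Observed score-covariance statistic, permutation null sample, alpha per component."""

    c_obs: np.ndarray
    null: np.ndarray  # (nperm, A)
    alpha: np.ndarray

    @property
    def nperm(self) -> int:
        return self.null.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": np.arange(1, len(self.c_obs) + 1),
            "c_obs": self.c_obs,
            "alpha": self.alpha,
            "null_mean": self.null.mean(axis=0),
            "null_q95": np.quantile(self.null, 0.95, axis=0),
        })


def _score_covariances(Xs: np.ndarray, ys: np.ndarray, a_max: int) -> np.ndarray:
    """|t_a' u_a| per component, u_a being the deflated response residual.

    For PLS1 the y-score of component a is the residual response itself, so
    |t_a' y_a| = |q_a| (t_a' t_a), computable from the fitted loadings.
    """
    model = fit_pls(Xs, ys, a_max)
    c = np.zeros(a_max)
    A = model.n_components_
    if A:
        tt = np.einsum("ij,ij->j", model.x_scores_, model.x_scores_)
        c[:A] = np.abs(model.y_loadings_) * tt
    return c


def randomization_test(X, y, a_max: int, nperm: int = 1000, seed: int = 0,
                       scale: bool = True) -> RandTestResult:
    """Permutation test for the significance of each latent component.

    The response is randomly permuted ``nperm`` times and the per-component
    statistic recomputed from a full refit; ``alpha_a`` is the exceedance
    fraction with the +1/(N+1) estimator.
    """
    if nperm < 99:
        raise ValueError("nperm must be at least 99")
    if a_max < 1:
        raise ValueError("a_max must be at least 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0.0:
        raise ValueError("constant response")
    n, p = X.shape
    a_max = int(min(a_max, p, n - 1))
    if scale:
        scaler = fit_scaler((X, y))
        Xs, ys = scaler.transform(X), scaler.transform_y(y)
    else:
        Xs, ys = X, y
    rng = np.random.default_rng(seed)
    c_obs = _score_covariances(Xs, ys, a_max)
    null = np.empty((nperm, a_max))
    for i in range(nperm):
        null[i] = _score_covariances(Xs, ys[rng.permutation(n)], a_max)
    alpha = (1.0 + np.sum(null >= c_obs[None, :], axis=0)) / (nperm + 1.0)
    return RandTestResult(c_obs=c_obs, null=null, alpha=alpha)


def select_ncomp(result: RandTestResult, alpha_crit: float = 0.05) -> int:
    """Largest A such that components 1..A are all significant (0 if none)."""
    ok = result.alpha <= alpha_crit
    A = 0
    for flag in ok:
        if not flag:
            break
        A += 1
    return A
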