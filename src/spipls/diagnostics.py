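"""Cook's-distance outlier screening and overfitting control.

Cook's distance is computed for the ordinary least-squares regression of the
response on the PLS score matrix (with intercept): for p = 52 predictors and
fewer than 80 training wines the raw-variable regression is ill-posed, whereas
the score regression has A + 1 << n parameters and a proper hat matrix.  The
closed form used here (via statsmodels' influence machinery),

    D_i = e_i^2 / (p' s^2) * h_ii / (1 - h_ii)^2,   p' = A + 1,

is algebraically identical to refitting without sample i and measuring the
shift of the fitted values.

Overfit control compares calibration and cross-validation fit per component
count: the gap |R2cal - R2cv| must not exceed 20%, and a knee ("inflection
point of the outer convex hull") of the (R2cv, gap) Pareto front marks the
Pareto-optimal complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .pls import PLSRegressionNIPALS

__all__ = [
    "GAP_THRESHOLD",
    "OutlierReport",
    "OverfitReport",
    "cooks_distance",
    "flag_outliers",
    "overfit_report",
    "pareto_knee",
    "plot_overfit",
]

#: maximum admissible |R2cal - R2cv| gap
GAP_THRESHOLD = 0.20


@dataclass
class OutlierReport:
    """Per-sample Cook's distances from the PLS score regression."""

    sample_ids: np.ndarray
    distances: np.ndarray
    n_params: int
    n_components: int
    rule: str = ""
    threshold: float = float("nan")
    flagged: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(-self.distances, kind="stable")
        return pd.DataFrame({
            "sample_id": self.sample_ids[order],
            "cooks_distance": self.distances[order],
            "flagged": [sid in self.flagged for sid in self.sample_ids[order]],
        })


def cooks_distance(X, y, n_components: int, sample_ids=None) -> OutlierReport:
    """Cook's distance of each sample in the OLS regression of y on the PLS scores."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if sample_ids is None:
        sample_ids = np.array([str(i) for i in range(n)], dtype=object)
    sample_ids = np.asarray(sample_ids, dtype=object)
    if n <= n_components + 1:
        raise ValueError("need n > n_components + 1 samples")
    model = PLSRegressionNIPALS(n_components=n_components, scale=True).fit(X, y)
    T = model.x_scores_
    Z = sm.add_constant(T) if T.shape[1] else np.ones((n, 1))
    res = sm.OLS(y, Z).fit()
    infl = res.get_influence()
    h = infl.hat_matrix_diag
    if np.any(h > 1.0 - 1e-10):
        bad = sample_ids[np.argmax(h)]
        raise ValueError(f"sample {bad!r} has leverage 1; Cook's distance undefined")
    if res.mse_resid <= 1e-24 * float(np.var(y) + 1e-300):
        d = np.zeros(n)  # numerically perfect fit: no influential residuals
    else:
        d = infl.cooks_distance[0]
    return OutlierReport(sample_ids=sample_ids, distances=np.asarray(d),
                         n_params=Z.shape[1], n_components=model.n_components_)


def flag_outliers(report: OutlierReport, rule: str = "4/n") -> list:
    """Flag samples by rule '4/n' (D > 4/n), '1.0' (D > 1), or 'top:k' (k largest).

    Updates ``report.rule``/``threshold``/``flagged`` and returns the flagged
    sample ids sorted by descending distance (ties broken by sample id).
    """
    d = report.distances
    n = len(d)
    order = sorted(range(n), key=lambda i: (-d[i], str(report.sample_ids[i])))
    if rule == "4/n":
        threshold = 4.0 / n
        flagged = [report.sample_ids[i] for i in order if d[i] > threshold]
    elif rule.startswith("top:"):
        try:
            kk = int(rule.split(":", 1)[1])
        except ValueError:
            raise ValueError(f"unknown outlier rule {rule!r}") from None
        threshold = float("nan")
        flagged = [report.sample_ids[i] for i in order[:kk]]
    else:
        try:
            threshold = float(rule)
        except ValueError:
            raise ValueError(f"unknown outlier rule {rule!r}") from None
        flagged = [report.sample_ids[i] for i in order if d[i] > threshold]
    report.rule = rule
    report.threshold = threshold
    report.flagged = flagged
    return flagged


# ---------------------------------------------------------------------------
# Overfitting control
# ---------------------------------------------------------------------------


@dataclass
class OverfitReport:
    """Calibration-vs-CV comparison per component count with knee detection."""

    table: pd.DataFrame  # columns: n_components, r2cal, r2cv, gap, rmsecal, rmsecv, ratio
    admissible_A: list
    pareto_A: int
    gap_threshold: float = GAP_THRESHOLD


def pareto_knee(r2cv, gap) -> int:
    """Knee of the (R2cv, gap) point set: the Pareto-optimal vertex (max R2cv,
    min gap) with maximum perpendicular distance to the chord joining the
    Pareto extremes; with fewer than 3 Pareto points, the max-R2cv point.

    Returns the 1-based component count.
    """
    r2cv = np.asarray(r2cv, dtype=float)
    gap = np.asarray(gap, dtype=float)
    m = len(r2cv)
    pareto = []
    for i in range(m):
        dominated = any(
            (r2cv[j] >= r2cv[i] and gap[j] <= gap[i]
             and (r2cv[j] > r2cv[i] or gap[j] < gap[i]))
            for j in range(m) if j != i)
        if not dominated:
            pareto.append(i)
    pareto.sort(key=lambda i: (r2cv[i], -gap[i]))
    if len(pareto) < 3:
        return pareto[-1] + 1
    p0 = np.array([r2cv[pareto[0]], gap[pareto[0]]])
    p1 = np.array([r2cv[pareto[-1]], gap[pareto[-1]]])
    chord = p1 - p0
    norm = float(np.hypot(*chord))
    dist = np.zeros(len(pareto))
    if norm > 0.0:
        for idx, i in enumerate(pareto):
            v = np.array([r2cv[i], gap[i]]) - p0
            dist[idx] = abs(chord[0] * v[1] - chord[1] * v[0]) / norm
    if dist.max() <= 0.0:
        return pareto[-1] + 1
    return pareto[int(np.argmax(dist))] + 1


def overfit_report(r2cal, r2cv, rmsecal, rmsecv,
                   gap_threshold: float = GAP_THRESHOLD) -> OverfitReport:
    """Build the overfitting-control report from per-component metrics (A = 1..A_max)."""
    r2cal = np.asarray(r2cal, dtype=float)
    r2cv = np.asarray(r2cv, dtype=float)
    rmsecal = np.asarray(rmsecal, dtype=float)
    rmsecv = np.asarray(rmsecv, dtype=float)
    a_max = len(r2cal)
    if a_max < 1:
        raise ValueError("need metrics for at least one component count")
    gap = np.abs(r2cal - r2cv)
    with np.errstate(divide="ignore"):
        ratio = np.where(rmsecal > 0.0, rmsecv / np.where(rmsecal > 0.0, rmsecal, 1.0),
                         np.inf)
    table = pd.DataFrame({
        "n_components": np.arange(1, a_max + 1),
        "r2cal": r2cal, "r2cv": r2cv, "gap": gap,
        "rmsecal": rmsecal, "rmsecv": rmsecv, "ratio": ratio,
    })
    admissible = [int(a) for a in range(1, a_max + 1) if gap[a - 1] <= gap_threshold]
    return OverfitReport(table=table, admissible_A=admissible,
                         pareto_A=pareto_knee(r2cv, gap), gap_threshold=gap_threshold)


def plot_overfit(report: OverfitReport, path) -> None:
    """Two-panel diagnostic: |R2cal - R2cv| vs R2cv and RMSEcv/RMSEcal vs RMSEcv."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = report.table
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(t["r2cv"], t["gap"], "o-")
    for _, row in t.iterrows():
        ax1.annotate(f"A={int(row['n_components'])}", (row["r2cv"], row["gap"]),
                     textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax1.axhline(report.gap_threshold, color="red", ls="--", lw=1)
    ax1.set_xlabel("R2cv")
    ax1.set_ylabel("|R2cal - R2cv|")
    ax2.plot(t["rmsecv"], t["ratio"], "o-")
    for _, row in t.iterrows():
        ax2.annotate(f"A={int(row['n_components'])}", (row["rmsecv"], row["ratio"]),
                     textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax2.set_xlabel("RMSEcv (g/L GAE)")
    ax2.set_ylabel("RMSEcv / RMSEcal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
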