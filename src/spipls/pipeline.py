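"""End-to-end SPI model-selection pipeline: m0 -> m1 -> m2 -> m3.

Stages mirror the calibration workflow:

* split the dataset 70/30 by stratum (test set untouched until the end);
* **m0** — PLS on all variables of the raw training set;
* Cook's-distance outlier screening on the score regression, removal;
* **m1** — refit on the cleaned training set;
* variable selection: stage 1 drops variables that are unimportant *and*
  insignificant (VIP < 1.0 and jack-knife p > 0.1), stage 2 backward-eliminates
  the worst remaining insignificant variable (p > 0.05) one at a time;
* **m2** — refit on the selected variables;
* permutation test + overfit control choose the final component count (the
  most parsimonious of the largest significant and largest admissible A);
* **m3** — final model, evaluated once on the held-out test set and exported
  as a portable raw-coefficient JSON.

The working component count at every refit is the RMSEcv minimizer of a
repeated randomized k-fold cross-validation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .dataset_io import SplitResult, WineDataset, stratified_split
from .diagnostics import (GAP_THRESHOLD, OutlierReport, OverfitReport,
                          cooks_distance, flag_outliers, overfit_report)
from .pls import FitMetrics, PLSRegressionNIPALS, r2_rmse
from .resampling import (CVResult, JackknifeResult, RandTestResult,
                         jackknife_significance, randomization_test,
                         repeated_kfold_cv, select_ncomp)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "StageSummary",
    "PipelineResult",
    "LinearPredictor",
    "stage1_filter",
    "stage2_backward",
    "run_pipeline",
    "evaluate_on_test",
    "export_model",
    "load_model",
    "load_eq1_model",
    "write_outputs",
]


class PipelineError(RuntimeError):
    """Raised when a selection stage cannot proceed (e.g. empty variable set)."""


@dataclass
class PipelineConfig:
    """All pipeline knobs with the study-shaped defaults."""

    train_frac: float = 0.7
    k: int = 8
    reps: int = 10
    nperm: int = 1000
    vip_threshold: float = 1.0
    p_stage1: float = 0.1
    p_stage2: float = 0.05
    alpha_crit: float = 0.05
    outlier_rule: str = "4/n"
    stage1_rule: str = "and"
    scale_in_cv: bool = True
    max_components: int = 10
    gap_threshold: float = GAP_THRESHOLD
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StageSummary:
    """One row of the stage-by-stage summary table."""

    name: str
    treatment: str
    n_samples: int
    n_variables: int
    n_components: int
    r2cal: float
    r2cv: float
    rmsecal: float
    rmsecv: float
    r2test: float | None = None
    rmsetest: float | None = None


@dataclass
class PipelineResult:
    stages: dict[str, StageSummary]
    status: str  # "ok" or "no_significant_model"
    status_reason: str
    selected_variables: list[str]
    final_ncomp: int
    outlier_report: OutlierReport | None
    removed_outliers: list
    selection_trace: list[dict]
    randtest: RandTestResult | None
    overfit: OverfitReport | None
    jackknife_final: JackknifeResult | None
    final_model: dict | None
    per_stratum_rmse: pd.DataFrame | None
    split_counts: pd.DataFrame
    test_hash_at_split: str
    test_hash_at_eval: str | None
    config: PipelineConfig

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for s in self.stages.values():
            rows.append({
                "model": s.name, "treatment": s.treatment,
                "n_samples": s.n_samples, "n_variables": s.n_variables,
                "n_components": s.n_components,
                "r2cal": s.r2cal, "r2cv": s.r2cv,
                "rmsecal": s.rmsecal, "rmsecv": s.rmsecv,
                "r2test": s.r2test, "rmsetest": s.rmsetest,
            })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        """Deterministic JSON summary of the run."""
        obj = {
            "status": self.status,
            "status_reason": self.status_reason,
            "stages": {k: dataclasses.asdict(v) for k, v in self.stages.items()},
            "selected_variables": self.selected_variables,
            "final_ncomp": self.final_ncomp,
            "removed_outliers": [str(s) for s in self.removed_outliers],
            "selection_trace": self.selection_trace,
            "alpha": None if self.randtest is None else list(map(float, self.randtest.alpha)),
            "test_hash_at_split": self.test_hash_at_split,
            "test_hash_at_eval": self.test_hash_at_eval,
            "config": self.config.to_dict(),
        }
        return json.dumps(obj, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Variable selection stages
# ---------------------------------------------------------------------------


def stage1_filter(variables: list[str], vip: np.ndarray, jack: JackknifeResult,
                  vip_thr: float = 1.0, p_thr: float = 0.1,
                  rule: str = "and") -> tuple[list[str], list[str]]:
    """Importance/significance filter.

    With ``rule='and'`` (default) a variable is removed iff it is both
    unimportant (VIP < vip_thr) and insignificant (p > p_thr); ``rule='or'``
    removes when either holds.  Returns (kept, removed) name lists.
    """
    vip = np.asarray(vip, dtype=float)
    p = np.asarray(jack.p_value, dtype=float)
    if not (len(variables) == len(vip) == len(p)):
        raise PipelineError("vip / jack-knife results do not cover all variables")
    low_vip = vip < vip_thr
    insig = p > p_thr
    remove = (low_vip & insig) if rule == "and" else (low_vip | insig)
    kept = [v for v, r in zip(variables, remove) if not r]
    removed = [v for v, r in zip(variables, remove) if r]
    if not kept:
        raise PipelineError(
            "stage-1 filter removed every variable; relax vip_threshold/p_stage1")
    return kept, removed


def _cv_and_fit(train: WineDataset, variables: list[str], cfg: PipelineConfig,
                seed: int):
    """CV on the given variable subset, full fit at a_max; returns
    (cv, model, A_best) where A_best minimizes RMSEcv."""
    sub = train.select(variables=variables)
    n = sub.n
    a_cap = min(cfg.max_components, sub.p, n - int(np.ceil(n / cfg.k)) - 1)
    cv = repeated_kfold_cv(sub.X, sub.y, a_cap, k=cfg.k, reps=cfg.reps,
                           seed=seed, scale_in_cv=cfg.scale_in_cv)
    model = PLSRegressionNIPALS(n_components=cv.a_max, scale=True).fit(sub.X, sub.y)
    return cv, model, cv.best_ncomp()


def stage2_backward(train: WineDataset, variables: list[str], cfg: PipelineConfig,
                    seed: int) -> tuple[list[str], list[dict]]:
    """Backward elimination of insignificant regression coefficients.

    Iteratively refit (working A = RMSEcv minimum), recompute jack-knife
    p-values, and remove the single worst variable with p > p_stage2; ties are
    broken by column order.  Stops when every remaining coefficient is
    significant.  Raises :class:`PipelineError` if elimination would empty the
    model.
    """
    if len(variables) < 2:
        raise PipelineError("stage-2 backward elimination needs at least 2 variables")
    current = list(variables)
    trace: list[dict] = []
    step = 0
    while True:
        cv, model, A = _cv_and_fit(train, current, cfg, seed)
        jack = jackknife_significance(cv, model.coef_scaled(A), A)
        p = jack.p_value
        over = np.where(p > cfg.p_stage2)[0]
        if len(over) == 0:
            break
        worst_local = over[np.argmax(p[over])]  # argmax keeps first on exact ties
        victim = current[worst_local]
        if len(current) == 1:
            raise PipelineError("backward elimination removed every variable")
        current.remove(victim)
        step += 1
        trace.append({
            "step": step, "reason": "backward_p", "removed": [victim],
            "p_value": float(p[worst_local]), "model_size_after": len(current),
            "A_used": int(A), "rmsecv_after": None,
        })
    if trace:
        trace[-1]["rmsecv_after"] = float(cv.rmsecv[A - 1])
    return current, trace


# ---------------------------------------------------------------------------
# Final-model export / import
# ---------------------------------------------------------------------------


@dataclass
class LinearPredictor:
    """A portable raw-coefficient linear model: y = intercept + X b_raw."""

    predictor_names: list[str]
    intercept: float
    coef_raw: np.ndarray
    meta: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.predictor_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.predictor_names):
            raise ValueError(
                f"expected {len(self.predictor_names)} columns, got {X.shape[1]}")
        return self.intercept + X @ self.coef_raw


def export_model(model: PLSRegressionNIPALS, variables: list[str],
                 n_components: int, path=None, provenance: dict | None = None) -> dict:
    """Serialize a fitted PLS model (scaled + raw coefficients, scaler, provenance)."""
    intercept, b_raw = model.raw_coefficients(n_components)
    s = model.scaler_
    obj = {
        "schema": "spipls-pls-model",
        "version": _pkg_version,
        "predictor_names": list(variables),
        "n_components": int(n_components),
        "b_scaled": [float(v) for v in model.coef_scaled(n_components)],
        "b_raw": [float(v) for v in b_raw],
        "intercept_raw": float(intercept),
        "scaler": {
            "means": [float(v) for v in s.means],
            "sds": [float(v) for v in s.sds],
            "y_mean": float(s.y_mean),
            "y_sd": float(s.y_sd),
        },
        "provenance": provenance or {},
    }
    if path is not None:
        Path(path).write_text(json.dumps(obj, indent=2))
    return obj


def load_model(source) -> LinearPredictor:
    """Load an exported model or a coefficient-only fixture into a predictor.

    Accepts a path or an already-parsed dict.  Coefficient-only files carry
    ``{"intercept": ..., "coefficients": {name: value}}``.
    """
    if isinstance(source, (str, Path)):
        obj = json.loads(Path(source).read_text())
    else:
        obj = dict(source)
    if "coefficients" in obj:
        names = list(obj["coefficients"])
        coef = np.array([obj["coefficients"][nm] for nm in names], dtype=float)
        return LinearPredictor(predictor_names=names,
                               intercept=float(obj["intercept"]), coef_raw=coef,
                               meta={k: v for k, v in obj.items()
                                     if k not in ("coefficients", "intercept")})
    if "b_raw" in obj:
        return LinearPredictor(predictor_names=list(obj["predictor_names"]),
                               intercept=float(obj["intercept_raw"]),
                               coef_raw=np.asarray(obj["b_raw"], dtype=float),
                               meta={k: v for k, v in obj.items()
                                     if k not in ("b_raw", "intercept_raw",
                                                  "predictor_names")})
    raise PipelineError("unrecognized model schema")


def load_eq1_model() -> LinearPredictor:
    """The shipped published raw-coefficient SPI calibration (19 assays)."""
    with resources.files("spipls.fixtures").joinpath("eq1_model.json").open() as fh:
        return load_model(json.load(fh))


# ---------------------------------------------------------------------------
# Test-set evaluation
# ---------------------------------------------------------------------------


def evaluate_on_test(model, test: WineDataset,
                     variables: list[str] | None = None,
                     n_components: int | None = None
                     ) -> tuple[FitMetrics, pd.DataFrame]:
    """Overall R2/RMSE on the test set plus a per-stratum RMSE table."""
    if isinstance(model, LinearPredictor):
        sub = test.select(variables=model.predictor_names)
        preds = model.predict(sub.X)
    else:
        sub = test.select(variables=variables) if variables is not None else test
        preds = model.predict(sub.X, n_components=n_components)
    metrics = r2_rmse(sub.y, preds)
    rows = []
    for s in sub.stratum_labels():
        mask = sub.strata == s
        err = sub.y[mask] - preds[mask]
        rows.append({"stratum": s, "n": int(mask.sum()),
                     "rmse": float(np.sqrt(np.mean(err**2)))})
    return metrics, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _stage_summary(name: str, treatment: str, train: WineDataset,
                   variables: list[str], cv: CVResult,
                   model: PLSRegressionNIPALS, A: int) -> StageSummary:
    sub = train.select(variables=variables)
    cal = r2_rmse(sub.y, model.predict(sub.X, n_components=A))
    return StageSummary(name=name, treatment=treatment, n_samples=sub.n,
                        n_variables=sub.p, n_components=A,
                        r2cal=cal.r2, r2cv=float(cv.r2cv[A - 1]),
                        rmsecal=cal.rmse, rmsecv=float(cv.rmsecv[A - 1]))


def run_pipeline(dataset: WineDataset, config: PipelineConfig | None = None
                 ) -> PipelineResult:
    """Run the full m0 -> m3 selection pipeline on a dataset."""
    cfg = config or PipelineConfig()
    seed_rng = np.random.default_rng(cfg.seed)
    seeds = {name: int(seed_rng.integers(2**31)) for name in
             ("split", "cv_m0", "cv_m1", "cv_stage2", "cv_m2", "randtest")}

    split = stratified_split(dataset, cfg.train_frac, seed=seeds["split"])
    train, test = split.train, split.test
    all_vars = list(train.predictor_names)

    stages: dict[str, StageSummary] = {}

    # ---- m0: raw training set, all variables
    cv0, model0, A0 = _cv_and_fit(train, all_vars, cfg, seeds["cv_m0"])
    stages["m0"] = _stage_summary("m0", "none", train, all_vars, cv0, model0, A0)

    # ---- outlier removal (Cook's distance on the score regression at pilot A)
    report = cooks_distance(train.X, train.y, A0, sample_ids=train.sample_ids)
    flagged = flag_outliers(report, cfg.outlier_rule)
    keep_mask = ~np.isin(train.sample_ids, flagged)
    train1 = train.select(rows=np.where(keep_mask)[0])

    def _refuse(reason: str) -> PipelineResult:
        return PipelineResult(
            stages=stages, status="no_significant_model", status_reason=reason,
            selected_variables=[], final_ncomp=0, outlier_report=report,
            removed_outliers=list(flagged), selection_trace=[], randtest=None,
            overfit=None, jackknife_final=None, final_model=None,
            per_stratum_rmse=None, split_counts=split.per_stratum_counts,
            test_hash_at_split=split.test_hash, test_hash_at_eval=None, config=cfg)

    # ---- m1: cleaned training set
    cv1, model1, A1 = _cv_and_fit(train1, all_vars, cfg, seeds["cv_m1"])
    stages["m1"] = _stage_summary("m1", "outlier_removal", train1, all_vars,
                                  cv1, model1, A1)

    # ---- stage 1 + stage 2 variable selection
    trace: list[dict] = []
    jack1 = jackknife_significance(cv1, model1.coef_scaled(A1), A1)
    vip1 = model1.vip(A1)
    try:
        kept1, removed1 = stage1_filter(all_vars, vip1, jack1,
                                        vip_thr=cfg.vip_threshold,
                                        p_thr=cfg.p_stage1, rule=cfg.stage1_rule)
    except PipelineError as exc:
        return _refuse(f"stage-1 filter: {exc}")
    if removed1:
        trace.append({"step": 0, "reason": "vip_and_p", "removed": removed1,
                      "model_size_after": len(kept1), "A_used": int(A1),
                      "rmsecv_after": None})
    try:
        kept2, trace2 = stage2_backward(train1, kept1, cfg, seeds["cv_stage2"])
    except PipelineError as exc:
        return _refuse(f"stage-2 backward elimination: {exc}")
    trace.extend(trace2)

    # ---- m2: selected variables
    cv2, model2, A2 = _cv_and_fit(train1, kept2, cfg, seeds["cv_m2"])
    stages["m2"] = _stage_summary("m2", "variable_selection", train1, kept2,
                                  cv2, model2, A2)

    # ---- permutation test + overfit control pick the final A
    sub2 = train1.select(variables=kept2)
    randtest = randomization_test(sub2.X, sub2.y, cv2.a_max, nperm=cfg.nperm,
                                  seed=seeds["randtest"])
    n_sig = select_ncomp(randtest, cfg.alpha_crit)
    r2cal_path = np.array([r2_rmse(sub2.y, model2.predict(sub2.X, n_components=a)).r2
                           for a in range(1, cv2.a_max + 1)])
    rmsecal_path = np.array([r2_rmse(sub2.y, model2.predict(sub2.X, n_components=a)).rmse
                             for a in range(1, cv2.a_max + 1)])
    over = overfit_report(r2cal_path, cv2.r2cv, rmsecal_path, cv2.rmsecv,
                          gap_threshold=cfg.gap_threshold)
    if n_sig == 0:
        res = _refuse("randomization test: no significant components")
        res.randtest = randtest
        res.overfit = over
        res.selection_trace = trace
        return res
    if not over.admissible_A:
        res = _refuse("overfit control: no admissible component count")
        res.randtest = randtest
        res.overfit = over
        res.selection_trace = trace
        return res
    A_final = min(n_sig, max(over.admissible_A))

    # ---- m3: final model + single test evaluation
    jack_final = jackknife_significance(cv2, model2.coef_scaled(A_final), A_final)
    stages["m3"] = _stage_summary("m3", "permtest_overfit_control", train1, kept2,
                                  cv2, model2, A_final)
    test_hash_eval = test.content_hash()
    metrics, per_stratum = evaluate_on_test(model2, test, variables=kept2,
                                            n_components=A_final)
    stages["m3"].r2test = metrics.r2
    stages["m3"].rmsetest = metrics.rmse
    final_model = export_model(
        model2, kept2, A_final,
        provenance={"seed": cfg.seed, "config": cfg.to_dict(),
                    "n_train": sub2.n, "alpha": [float(a) for a in randtest.alpha]})

    return PipelineResult(
        stages=stages, status="ok", status_reason="",
        selected_variables=kept2, final_ncomp=A_final,
        outlier_report=report, removed_outliers=list(flagged),
        selection_trace=trace, randtest=randtest, overfit=over,
        jackknife_final=jack_final, final_model=final_model,
        per_stratum_rmse=per_stratum, split_counts=split.per_stratum_counts,
        test_hash_at_split=split.test_hash, test_hash_at_eval=test_hash_eval,
        config=cfg)


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write the standard report files for a pipeline run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.summary_table().to_csv(outdir / "summary_table3.tsv", sep="\t", index=False)
    (outdir / "selection_trace.json").write_text(
        json.dumps(result.selection_trace, indent=2))
    if result.outlier_report is not None:
        result.outlier_report.to_frame().to_csv(outdir / "outliers.tsv", sep="\t",
                                                index=False)
    if result.randtest is not None:
        result.randtest.to_frame().to_csv(outdir / "randtest.tsv", sep="\t", index=False)
    if result.overfit is not None:
        result.overfit.table.to_csv(outdir / "overfit.tsv", sep="\t", index=False)
    if result.final_model is not None:
        (outdir / "final_model.json").write_text(json.dumps(result.final_model, indent=2))
    if result.per_stratum_rmse is not None:
        result.per_stratum_rmse.to_csv(outdir / "per_stratum_rmse.tsv", sep="\t",
                                       index=False)
    m3 = result.stages.get("m3")
    if m3 is not None and m3.r2test is not None:
        pd.DataFrame([{"r2test": m3.r2test, "rmsetest": m3.rmsetest}]).to_csv(
            outdir / "test_eval.tsv", sep="\t", index=False)
    (outdir / "run.json").write_text(result.to_json())
    (outdir / "run.log").write_text(
        f"spipls {_pkg_version}\nstatus: {result.status} {result.status_reason}\n"
        f"selected variables ({len(result.selected_variables)}): "
        f"{', '.join(result.selected_variables)}\n"
        f"final components: {result.final_ncomp}\n")
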