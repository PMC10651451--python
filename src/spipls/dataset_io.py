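"""Tabular wine-chemistry dataset container, CSV I/O, stratified splitting, autoscaling.

The on-disk format is a plain UTF-8 CSV with '.' decimal and comma separator:
``sample_id,stratum,<p predictor columns>,spi``.  The response column ``spi``
is the saliva precipitation index in g/L gallic-acid equivalent (GAE); the
stratum label encodes grape variety x region and drives the proportional
train/test split.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DatasetError",
    "WineDataset",
    "ScalingModel",
    "SplitResult",
    "read_dataset",
    "write_dataset",
    "stratified_split",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
]


class DatasetError(ValueError):
    """Raised for malformed datasets or invalid split/scaling requests."""


@dataclass
class WineDataset:
    """One row per wine sample: id, stratum label, p numeric predictors, SPI response.

    Attributes
    ----------
    sample_ids : array of str, unique identifiers.
    strata : array of str, variety-x-region labels (one per sample).
    predictor_names : list of str, column names including units.
    X : (n, p) float array of predictor values.
    y : (n,) float array, SPI in g/L GAE.
    """

    sample_ids: np.ndarray
    strata: np.ndarray
    predictor_names: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.strata = np.asarray(self.strata, dtype=object)
        self.predictor_names = list(self.predictor_names)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.sample_ids)
        if self.X.ndim != 2 or self.X.shape[0] != n:
            raise DatasetError(f"X must be 2-D with {n} rows, got shape {self.X.shape}")
        if self.X.shape[1] != len(self.predictor_names):
            raise DatasetError("number of predictor names does not match X columns")
        if len(self.y) != n or len(self.strata) != n:
            raise DatasetError("sample_ids, strata and y must have equal length")
        if len(set(self.sample_ids)) != n:
            raise DatasetError("duplicate sample ids")
        if not np.all(np.isfinite(self.X)):
            bad = [self.predictor_names[j] for j in np.where(~np.isfinite(self.X).all(axis=0))[0]]
            raise DatasetError(f"non-finite predictor values in columns: {bad}")
        if not np.all(np.isfinite(self.y)):
            raise DatasetError("non-finite response values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def stratum_labels(self) -> list[str]:
        """Distinct strata in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.strata:
            seen.setdefault(s, None)
        return list(seen)

    def select(self, rows=None, variables=None) -> "WineDataset":
        """Return a copy restricted to the given row indices and/or variable names."""
        rows = np.arange(self.n) if rows is None else np.asarray(rows)
        if variables is None:
            cols = np.arange(self.p)
            names = list(self.predictor_names)
        else:
            name_to_idx = {nm: j for j, nm in enumerate(self.predictor_names)}
            try:
                cols = np.array([name_to_idx[v] for v in variables])
            except KeyError as exc:
                raise DatasetError(f"unknown predictor {exc.args[0]!r}") from None
            names = list(variables)
        return WineDataset(
            sample_ids=self.sample_ids[rows].copy(),
            strata=self.strata[rows].copy(),
            predictor_names=names,
            X=self.X[np.ix_(rows, cols)].copy(),
            y=self.y[rows].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.predictor_names)
        df.insert(0, "stratum", self.strata)
        df.insert(0, "sample_id", self.sample_ids)
        df["spi"] = self.y
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WineDataset":
        required = {"sample_id", "stratum", "spi"}
        missing = required - set(df.columns)
        if missing:
            raise DatasetError(f"missing required columns: {sorted(missing)}")
        pred_cols = [c for c in df.columns if c not in required]
        bad_cols = []
        for c in pred_cols + ["spi"]:
            col = pd.to_numeric(df[c], errors="coerce")
            if col.isna().any():
                bad_cols.append(c)
        if bad_cols:
            raise DatasetError(f"non-numeric or missing values in columns: {bad_cols}")
        X = df[pred_cols].to_numpy(dtype=float)
        if X.shape[0] < 3:
            raise DatasetError("dataset needs at least 3 samples")
        const = [pred_cols[j] for j in range(X.shape[1]) if np.ptp(X[:, j]) == 0.0]
        if const:
            raise DatasetError(f"constant predictor columns (zero variance): {const}")
        return cls(
            sample_ids=df["sample_id"].astype(str).to_numpy(dtype=object),
            strata=df["stratum"].astype(str).to_numpy(dtype=object),
            predictor_names=pred_cols,
            X=X,
            y=df["spi"].to_numpy(dtype=float),
        )

    def content_hash(self) -> str:
        """SHA-256 of the canonical CSV serialization (used for test-set isolation)."""
        csv = self.to_frame().to_csv(index=False, float_format="%.12g")
        return hashlib.sha256(csv.encode()).hexdigest()


def read_dataset(path) -> WineDataset:
    """Read a dataset CSV (``sample_id,stratum,<predictors>,spi``), validating types."""
    return WineDataset.from_frame(pd.read_csv(path))


def write_dataset(dataset: WineDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Stratified split
# ---------------------------------------------------------------------------


@dataclass
class SplitResult:
    train: WineDataset
    test: WineDataset
    per_stratum_counts: pd.DataFrame = field(repr=False)
    test_hash: str = ""


def _largest_remainder_allocation(counts: list[int], frac: float) -> list[int]:
    """Per-stratum training counts summing to the half-up rounded global target.

    Each stratum gets floor(frac*count); the remaining units go to the strata
    with the largest fractional remainders (ties broken by position).
    """
    n = sum(counts)
    target = int(np.floor(frac * n + 0.5))
    quotas = [frac * c for c in counts]
    alloc = [int(np.floor(q)) for q in quotas]
    extras = target - sum(alloc)
    order = sorted(range(len(counts)), key=lambda i: (-(quotas[i] - alloc[i]), i))
    for i in order:
        if extras <= 0:
            break
        if alloc[i] < counts[i]:
            alloc[i] += 1
            extras -= 1
    if extras > 0:  # pathological frac ~ 1; give to any stratum with room
        for i in range(len(counts)):
            while extras > 0 and alloc[i] < counts[i]:
                alloc[i] += 1
                extras -= 1
    return alloc


def stratified_split(dataset: WineDataset, train_frac: float = 0.7, seed: int = 0) -> SplitResult:
    """Random stratified train/test split preserving per-stratum proportions.

    Training counts are allocated per stratum by largest-remainder rounding so
    that the total equals the half-up rounding of ``train_frac * n``; within a
    stratum membership is randomized under ``seed``.
    """
    if not 0.0 < train_frac < 1.0:
        raise DatasetError("train_frac must lie strictly between 0 and 1")
    labels = dataset.stratum_labels()
    if any(str(s).strip() == "" for s in labels):
        raise DatasetError("empty stratum label")
    rng = np.random.default_rng(seed)
    idx_by_stratum = {s: np.where(dataset.strata == s)[0] for s in labels}
    counts = [len(idx_by_stratum[s]) for s in labels]
    alloc = _largest_remainder_allocation(counts, train_frac)
    train_idx: list[int] = []
    test_idx: list[int] = []
    rows = []
    for s, c, a in zip(labels, counts, alloc):
        perm = rng.permutation(idx_by_stratum[s])
        train_idx.extend(perm[:a])
        test_idx.extend(perm[a:])
        rows.append({"stratum": s, "n_total": c, "n_train": a, "n_test": c - a})
    train = dataset.select(rows=np.sort(train_idx))
    test = dataset.select(rows=np.sort(test_idx))
    counts_df = pd.DataFrame(rows)
    return SplitResult(train=train, test=test, per_stratum_counts=counts_df,
                       test_hash=test.content_hash())


# ---------------------------------------------------------------------------
# Autoscaling
# ---------------------------------------------------------------------------


@dataclass
class ScalingModel:
    """Column means/SDs (ddof=1) of the training set, for autoscaling X and y.

    Test data must be transformed with *training* statistics only; fitting this
    model on held-out data would leak information into calibration.
    """

    means: np.ndarray
    sds: np.ndarray
    y_mean: float
    y_sd: float

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.means) / self.sds

    def inverse_transform(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, dtype=float) * self.sds + self.means

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_sd

    def inverse_transform_y(self, ys: np.ndarray) -> np.ndarray:
        return np.asarray(ys, dtype=float) * self.y_sd + self.y_mean


def fit_scaler(train) -> ScalingModel:
    """Fit autoscaling statistics on a training :class:`WineDataset` or ``(X, y)`` pair."""
    if isinstance(train, WineDataset):
        X, y, names = train.X, train.y, train.predictor_names
    else:
        X, y = train
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        names = [f"col{j}" for j in range(X.shape[1])]
    if X.shape[0] < 2:
        raise DatasetError("scaling needs at least 2 samples")
    sds = X.std(axis=0, ddof=1)
    if np.any(sds == 0.0):
        bad = [names[j] for j in np.where(sds == 0.0)[0]]
        raise DatasetError(f"constant columns cannot be autoscaled: {bad}")
    y_sd = float(np.std(y, ddof=1))
    if y_sd == 0.0:
        raise DatasetError("constant response cannot be autoscaled")
    return ScalingModel(means=X.mean(axis=0), sds=sds, y_mean=float(np.mean(y)), y_sd=y_sd)


def apply_scaler(scaler: ScalingModel, X: np.ndarray, y: np.ndarray | None = None):
    if y is None:
        return scaler.transform(X)
    return scaler.transform(X), scaler.transform_y(y)


def invert_scaler(scaler: ScalingModel, Xs: np.ndarray, ys: np.ndarray | None = None):
    if ys is None:
        return scaler.inverse_transform(Xs)
    return scaler.inverse_transform(Xs), scaler.inverse_transform_y(ys)
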