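"""Binary transfer layer (BIMGO) and the wrapper feature-selection engine.

A candidate feature subset is encoded as a continuous position in a small box
(default [-5, 5] per feature); a sigmoid transfer function maps each
coordinate to an inclusion probability which is thresholded at 0.5 — so a
feature is selected exactly when its coordinate is non-negative. The wrapper
objective of a mask is the held-out error rate of a classifier trained on the
selected columns (no feature-count penalty: parsimony must emerge from the
search). The continuous search itself is plain IMGO; subset evaluations are
memoized by mask so repeated visits to the same subset cost nothing.

Dataset IO covers headered CSV and ARFF with UCI-style conventions: numeric
columns pass through, categoricals are integer-encoded, missing values are
imputed by column median (numeric) or mode (categorical) with the imputation
sites recorded in a mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.io import arff as scipy_arff
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .imgo import imgo_minimize
from .mgo import OptimizerConfig, OptResult
from .problems import ProblemSpec

__all__ = [
    "FeatureDataset",
    "ConfusionCounts",
    "FSResult",
    "EvalProtocol",
    "sigmoid",
    "binarize",
    "fitness_error_rate",
    "sensitivity",
    "evaluate_subset",
    "bimgo_select",
    "load_dataset",
]


@dataclass
class FeatureDataset:
    """An instance-by-feature numeric matrix with labels, after imputation/encoding."""

    matrix: np.ndarray  # (n_instances, n_features), finite
    labels: np.ndarray  # (n_instances,)
    feature_names: list[str]
    missing_mask: np.ndarray  # boolean, True where a value was imputed
    positive_class: object = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.matrix.shape, dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries after imputation")
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError("labels length must match the number of instances")
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) < 2 or counts.min() < 2:
            raise ValueError("need at least two classes with >= 2 instances each")
        if self.positive_class is None:
            # default: the minority class is the disease-positive one
            self.positive_class = classes[int(np.argmin(counts))]

    @property
    def n_instances(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for the declared positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class FSResult:
    """Outcome of one feature-selection run."""

    mask: np.ndarray  # boolean, length n_features
    fitness: float
    sensitivity: float  # nan when the test partition has no positives
    n_selected: int
    counts: Optional[ConfusionCounts]
    trace: np.ndarray
    seed: int
    position: Optional[np.ndarray] = None


def sigmoid(x):
    """Numerically stable logistic transfer S(x) = 1 / (1 + e^-x)."""
    return expit(x)


def binarize(position: np.ndarray) -> np.ndarray:
    """Threshold the transfer probability at 0.5: bit_d = 1 iff S(x_d) >= 0.5,
    which for finite x is exactly x_d >= 0 (the boundary belongs to 1)."""
    return np.asarray(position) >= 0.0


def fitness_error_rate(counts: ConfusionCounts) -> float:
    """Classification error 1 - (TP+TN)/(TP+TN+FP+FN)."""
    if counts.total == 0:
        raise ValueError("no evaluated instances")
    return 1.0 - (counts.tp + counts.tn) / counts.total


def sensitivity(counts: ConfusionCounts) -> float:
    """Recall on the positive class, TP/(TP+FN); nan when undefined."""
    if counts.tp + counts.fn == 0:
        return math.nan
    return counts.tp / (counts.tp + counts.fn)


def _make_classifier(name: str):
    if name == "svm-rbf":
        return SVC(kernel="rbf")
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "knn-1":
        return KNeighborsClassifier(n_neighbors=1)
    if name == "logistic":
        return LogisticRegression(max_iter=500)
    raise ValueError(f"unknown classifier: {name!r}")


@dataclass
class EvalProtocol:
    """How a candidate subset is scored.

    Default: a stratified 80/20 hold-out split, fixed once per protocol
    instance by ``seed``, scored with an RBF-kernel support vector classifier.
    Set ``n_folds`` for stratified k-fold cross-validation instead (counts are
    pooled over folds). The classifier is pluggable (``svm-rbf``, ``knn``,
    ``knn-1``, ``logistic``) and must be deterministic given the data.
    """

    classifier: str = "svm-rbf"
    test_size: float = 0.2
    n_folds: Optional[int] = None
    seed: int = 0
    _splits: Optional[list] = field(default=None, repr=False, compare=False)

    def splits(self, data: FeatureDataset) -> list[tuple[np.ndarray, np.ndarray]]:
        if self._splits is None:
            idx = np.arange(data.n_instances)
            if self.n_folds is None:
                train, test = train_test_split(
                    idx,
                    test_size=self.test_size,
                    random_state=self.seed % (2**32),
                    stratify=data.labels,
                )
                self._splits = [(train, test)]
            else:
                skf = StratifiedKFold(
                    n_splits=self.n_folds, shuffle=True, random_state=self.seed % (2**32)
                )
                self._splits = [
                    (tr, te) for tr, te in skf.split(idx, data.labels)
                ]
        return self._splits


def evaluate_subset(
    data: FeatureDataset,
    mask: np.ndarray,
    protocol: EvalProtocol,
) -> tuple[float, ConfusionCounts]:
    """Held-out error rate and confusion counts of the classifier on a subset.

    An all-zero mask short-circuits to the worst fitness 1.0 with empty counts
    (the penalty that keeps the search away from empty subsets). The confusion
    counts are one-vs-rest for the dataset's positive class; for binary labels
    the error rate derived from them is exactly 1 - accuracy.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != data.n_features:
        raise ValueError("mask length must equal the number of features")
    if not mask.any():
        return 1.0, ConfusionCounts(0, 0, 0, 0)
    X = data.matrix[:, mask]
    y = data.labels
    pos = data.positive_class
    tp = tn = fp = fn = 0
    correct = 0
    total = 0
    for train, test in protocol.splits(data):
        if len(np.unique(y[train])) < 2:
            raise ValueError("degenerate single-class training partition")
        clf = _make_classifier(protocol.classifier)
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        truth = y[test]
        actual_pos = truth == pos
        pred_pos = pred == pos
        tp += int(np.sum(actual_pos & pred_pos))
        fn += int(np.sum(actual_pos & ~pred_pos))
        fp += int(np.sum(~actual_pos & pred_pos))
        tn += int(np.sum(~actual_pos & ~pred_pos))
        correct += int(np.sum(pred == truth))
        total += len(test)
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return 1.0 - correct / total, counts


def bimgo_select(
    data: FeatureDataset,
    cfg: OptimizerConfig,
    protocol: Optional[EvalProtocol] = None,
    memoize: bool = True,
) -> FSResult:
    """Wrapper feature selection with the binary IMGO.

    Runs the continuous IMGO over D = n_features dimensions inside
    ``cfg.fs_bounds``; every position is decoded to a mask by the sigmoid
    transfer and scored by ``evaluate_subset``. Evaluations are memoized by
    mask, so the optimizer pays only for distinct subsets.
    """
    if protocol is None:
        protocol = EvalProtocol(seed=cfg.seed)
    d = data.n_features
    lo, hi = cfg.fs_bounds
    cache: dict[bytes, float] = {}

    def objective(x: np.ndarray) -> float:
        mask = binarize(x)
        if memoize:
            key = np.packbits(mask).tobytes()
            v = cache.get(key)
            if v is None:
                v = evaluate_subset(data, mask, protocol)[0]
                cache[key] = v
            return v
        return evaluate_subset(data, mask, protocol)[0]

    spec = ProblemSpec(
        name="feature-selection",
        dim=d,
        lower=np.full(d, float(lo)),
        upper=np.full(d, float(hi)),
        objective=objective,
        known_optimum=None,
    )
    res: OptResult = imgo_minimize(spec, cfg)
    mask = binarize(res.best_position)
    fitness, counts = evaluate_subset(data, mask, protocol)
    return FSResult(
        mask=mask,
        fitness=fitness,
        sensitivity=sensitivity(counts) if mask.any() else math.nan,
        n_selected=int(mask.sum()),
        counts=counts if mask.any() else None,
        trace=res.trace,
        seed=cfg.seed,
        position=res.best_position,
    )


# ---------------------------------------------------------------------------
# dataset IO
# ---------------------------------------------------------------------------

def _impute_frame(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Numeric passthrough / categorical integer-encoding with median/mode
    imputation; returns the matrix and the imputation-site mask."""
    n, p = df.shape
    matrix = np.empty((n, p))
    mask = np.zeros((n, p), dtype=bool)
    for j, col in enumerate(df.columns):
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            miss = s.isna().to_numpy()
            vals = s.to_numpy(dtype=float)
            if miss.all():
                raise ValueError(f"column {col!r} is entirely missing")
            if miss.any():
                vals[miss] = np.nanmedian(vals)
            matrix[:, j] = vals
            mask[:, j] = miss
        else:
            s = s.astype("object")
            miss = s.isna().to_numpy()
            if miss.all():
                raise ValueError(f"column {col!r} is entirely missing")
            observed = s[~miss]
            # deterministic mode: most frequent, ties broken by sorted order
            counts = observed.value_counts()
            top = counts[counts == counts.max()].index
            fill = sorted(top, key=str)[0]
            filled = s.where(~miss, fill)
            cats = sorted(pd.unique(filled), key=str)
            codes = {c: k for k, c in enumerate(cats)}
            matrix[:, j] = [codes[v] for v in filled]
            mask[:, j] = miss
    return matrix, mask


def _read_arff(path: Path) -> pd.DataFrame:
    raw, meta = scipy_arff.loadarff(str(path))
    df = pd.DataFrame(raw)
    for col in df.columns:
        if df[col].dtype == object:
            decoded = df[col].str.decode("utf-8")
            decoded = decoded.replace("?", np.nan)
            # nominal attributes whose values are all numerals (e.g. a 0/1
            # class) come back as strings; coerce so CSV and ARFF encodings
            # of the same table load identically
            numeric = pd.to_numeric(decoded, errors="coerce")
            if numeric.notna().equals(decoded.notna()):
                decoded = numeric
            df[col] = decoded
    return df


def load_dataset(
    path: Union[str, Path],
    dialect: Optional[str] = None,
    label_column: str = "label",
    positive_class: object = None,
) -> FeatureDataset:
    """Load a labeled tabular dataset from CSV (headered) or ARFF.

    ``dialect`` is inferred from the file extension when omitted. Missing
    numeric values (empty CSV cells, ARFF '?') are imputed by column median,
    categoricals by mode; the imputation sites are recorded in
    ``missing_mask``.
    """
    path = Path(path)
    if dialect is None:
        dialect = "arff" if path.suffix.lower() == ".arff" else "csv"
    if dialect == "csv":
        df = pd.read_csv(path)
    elif dialect == "arff":
        df = _read_arff(path)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    labels_raw = df[label_column]
    if labels_raw.isna().any():
        raise ValueError("labels must not be missing")
    features = df.drop(columns=[label_column])
    matrix, mask = _impute_frame(features)
    labels = labels_raw.to_numpy()
    if pd.api.types.is_numeric_dtype(labels_raw) and np.allclose(labels, labels.astype(int)):
        labels = labels.astype(int)
    if positive_class is not None and pd.api.types.is_numeric_dtype(labels_raw):
        positive_class = int(positive_class)
    return FeatureDataset(
        matrix=matrix,
        labels=labels,
        feature_names=[str(c) for c in features.columns],
        missing_mask=mask,
        positive_class=positive_class,
    )
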