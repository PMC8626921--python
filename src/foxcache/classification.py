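"""Behaviour classification: algorithm roster, cross-validation,
confusion-matrix metrics, model selection, dataset annotation and
activity budgets.

Eight classifiers are compared under stratified 5-fold cross-validation
with identical fold assignments (a paired comparison): 3-nearest
neighbours, linear SVM, RBF-kernel SVM, decision tree, random forest,
Gaussian naive Bayes, linear discriminant analysis, and a single-
hidden-layer neural network. Out-of-fold predictions are pooled into
one confusion matrix per algorithm, from which per-category one-vs-rest
accuracy, precision and recall are computed:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)

Weighted averages across categories use the actual category counts as
weights; weighted recall therefore equals the overall proportion of
correct classifications (trace / total).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .behaviors import CATEGORIES, DIGGING
from .features import compute_feature_matrix

log = logging.getLogger("foxcache")

ALGORITHM_NAMES = (
    "knn3",
    "svm_linear",
    "svm_rbf",
    "decision_tree",
    "random_forest",
    "naive_bayes",
    "lda",
    "neural_net",
)

#: algorithms whose inputs are standardized with train-fold statistics
_SCALED = {"knn3", "svm_linear", "svm_rbf", "neural_net"}


def make_classifier(name: str, seed: int = 0):
    """Instantiate one algorithm from the fixed roster.

    Distance- and gradient-based learners (kNN, SVMs, network) are
    wrapped in a train-fold StandardScaler; tree-based learners, naive
    Bayes and LDA take raw features.
    """
    if name == "knn3":
        clf = KNeighborsClassifier(n_neighbors=3)
    elif name == "svm_linear":
        clf = SVC(kernel="linear", random_state=seed)
    elif name == "svm_rbf":
        clf = SVC(kernel="rbf", random_state=seed)
    elif name == "decision_tree":
        clf = DecisionTreeClassifier(random_state=seed)
    elif name == "random_forest":
        clf = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    elif name == "naive_bayes":
        clf = GaussianNB()
    elif name == "lda":
        clf = LinearDiscriminantAnalysis()
    elif name == "neural_net":
        clf = MLPClassifier(
            hidden_layer_sizes=(32,), max_iter=600, random_state=seed
        )
    else:
        raise ValueError(f"unknown algorithm {name!r}; choose from {ALGORITHM_NAMES}")
    if name in _SCALED:
        return make_pipeline(StandardScaler(), clf)
    return clf


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows = actual category, columns = predicted, in the
    canonical order (running, walking, digging, motionless)."""

    counts: np.ndarray
    categories: tuple[str, ...] = CATEGORIES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.categories)
        if self.counts.shape != (k, k):
            raise ValueError(f"confusion matrix must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")

    @classmethod
    def from_labels(cls, actual, predicted, categories=CATEGORIES) -> "ConfusionMatrix":
        idx = {c: i for i, c in enumerate(categories)}
        k = len(categories)
        m = np.zeros((k, k), dtype=int)
        for a, p in zip(actual, predicted):
            m[idx[a], idx[p]] += 1
        return cls(m, tuple(categories))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, category: str) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for one category collapsed against the rest."""
        i = self.categories.index(category)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, tn, fp, fn

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.categories, columns=self.categories)
        df["Total"] = df.sum(axis=1)
        df.loc["Total"] = df.sum(axis=0)
        return df


def round_half_up(x, ndigits: int = 2):
    """Decimal-style rounding (0.625 -> 0.63), the convention of
    printed report tables; numpy/Python round() rounds half to even."""
    factor = 10.0**ndigits
    return np.floor(np.asarray(x, dtype=float) * factor + 0.5) / factor


@dataclass
class ClassMetrics:
    """Per-category accuracy/precision/recall (%) plus count-weighted
    averages. Values are carried at full precision; round only when
    reporting."""

    per_class: pd.DataFrame  # index = category; accuracy, precision, recall
    weighted_accuracy: float
    weighted_precision: float
    weighted_recall: float

    def rounded(self, ndigits: int = 2) -> pd.DataFrame:
        df = self.per_class.copy()
        df.loc["weighted_average"] = [
            self.weighted_accuracy,
            self.weighted_precision,
            self.weighted_recall,
        ]
        return df.apply(lambda c: round_half_up(c, ndigits))


def compute_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest accuracy, precision and recall per category, in %.

    Precision is undefined (NaN, with a warning) for a category into
    which nothing was classified. Weighted averages use the actual
    category counts as weights, so weighted recall equals
    100 * trace / total.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    rows = {}
    for cat in cm.categories:
        tp, tn, fp, fn = cm.one_vs_rest(cat)
        acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
        if tp + fp == 0:
            warnings.warn(
                f"precision undefined for {cat!r}: no predictions into the category",
                stacklevel=2,
            )
            prec = np.nan
        else:
            prec = 100.0 * tp / (tp + fp)
        rec = 100.0 * tp / (tp + fn) if tp + fn else np.nan
        rows[cat] = {"accuracy": acc, "precision": prec, "recall": rec}
    per_class = pd.DataFrame.from_dict(rows, orient="index")
    weights = cm.counts.sum(axis=1).astype(float)
    w = weights / weights.sum()
    return ClassMetrics(
        per_class=per_class,
        weighted_accuracy=float(np.nansum(w * per_class["accuracy"].to_numpy())),
        weighted_precision=float(np.nansum(w * per_class["precision"].to_numpy())),
        weighted_recall=float(np.nansum(w * per_class["recall"].to_numpy())),
    )


@dataclass
class CVResult:
    algorithm: str
    confusion: ConfusionMatrix
    metrics: ClassMetrics
    fold_assignment: np.ndarray
    seed: int


def crossvalidate(
    features: np.ndarray,
    labels: np.ndarray,
    algorithms=ALGORITHM_NAMES,
    k: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> dict[str, CVResult]:
    """k-fold cross-validation with fold assignments shared across
    algorithms, pooling out-of-fold predictions into one confusion
    matrix per algorithm.

    Folds are stratified by category by default: with few sequences of
    a rare behaviour, unstratified folds can lack it entirely. Pass
    ``stratified=False`` for plain equal splitting.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=object)
    for name in algorithms:
        if name not in ALGORITHM_NAMES:
            raise ValueError(f"unknown algorithm {name!r}")
    counts = pd.Series(labels).value_counts()
    if stratified and (counts < k).any():
        small = list(counts[counts < k].index)
        raise ValueError(
            f"categories {small} have fewer than k={k} sequences; "
            "disable stratification to proceed"
        )
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(splitter.split(features, labels))
    assignment = np.empty(len(labels), dtype=int)
    for f, (_, val) in enumerate(folds):
        assignment[val] = f

    results: dict[str, CVResult] = {}
    for name in algorithms:
        predicted = np.empty(len(labels), dtype=object)
        for train, val in folds:
            clf = make_classifier(name, seed=seed)
            clf.fit(features[train], labels[train])
            predicted[val] = clf.predict(features[val])
        cmat = ConfusionMatrix.from_labels(labels, predicted)
        results[name] = CVResult(
            algorithm=name,
            confusion=cmat,
            metrics=compute_metrics(cmat),
            fold_assignment=assignment,
            seed=seed,
        )
        log.info(
            "cv %-13s weighted acc/prec/rec %.2f/%.2f/%.2f",
            name,
            results[name].metrics.weighted_accuracy,
            results[name].metrics.weighted_precision,
            results[name].metrics.weighted_recall,
        )
    return results


def select_model(
    results: dict[str, CVResult] | list[CVResult],
    criterion: str = "weighted_precision",
) -> str:
    """Pick the algorithm maximizing the criterion.

    The default criterion is weighted-average precision — false
    positives for the rare focal behaviour are the costly error when
    mapping caching events. Ties break on digging precision, then
    weighted accuracy.
    """
    if isinstance(results, dict):
        results = list(results.values())
    if not results:
        raise ValueError("no cross-validation results to select from")

    def key(r: CVResult):
        primary = getattr(r.metrics, criterion, None)
        if primary is None:
            raise ValueError(f"unknown selection criterion {criterion!r}")
        return (
            primary,
            r.metrics.per_class.loc[DIGGING, "precision"],
            r.metrics.weighted_accuracy,
        )

    return max(results, key=key).algorithm


def fit_final_model(features: np.ndarray, labels: np.ndarray, name: str, seed: int = 0):
    """Refit the selected algorithm on the full training set."""
    clf = make_classifier(name, seed=seed)
    clf.fit(np.asarray(features, dtype=float), np.asarray(labels, dtype=object))
    return clf


def annotate_bursts(
    model,
    signals: np.ndarray,
    windows_per_burst: int = 10,
    burst_ids=None,
) -> pd.DataFrame:
    """Split each burst into its 3-s windows and predict a label per
    window (10 labels per 30-s burst).

    Bursts whose sample count is not a multiple of the window are
    skipped with a logged id. Returns a frame with burst index/id,
    window_index and label.
    """
    signals = np.asarray(signals, dtype=float)
    n_bursts, _, n_samples = signals.shape
    if n_samples % windows_per_burst != 0:
        raise ValueError(
            f"burst length {n_samples} not divisible into {windows_per_burst} windows"
        )
    spw = n_samples // windows_per_burst
    keep = np.ones(n_bursts, dtype=bool)
    for i in range(n_bursts):
        if not np.all(np.isfinite(signals[i])):
            keep[i] = False
            bid = burst_ids[i] if burst_ids is not None else i
            log.warning("burst %s skipped: non-finite samples", bid)
    idx = np.nonzero(keep)[0]
    windows = signals[idx].reshape(len(idx), 3, windows_per_burst, spw)
    windows = windows.transpose(0, 2, 1, 3).reshape(-1, 3, spw)
    feats = compute_feature_matrix(windows)
    labels = model.predict(feats)
    out = pd.DataFrame(
        {
            "burst_index": np.repeat(idx, windows_per_burst),
            "window_index": np.tile(np.arange(windows_per_burst), len(idx)),
            "label": labels,
        }
    )
    if burst_ids is not None:
        ids = np.asarray(burst_ids, dtype=object)
        out.insert(0, "burst_id", ids[out["burst_index"].to_numpy()])
    return out


def activity_budget(labels) -> pd.Series:
    """Proportion of windows per behaviour (sums to 1 before rounding)."""
    labels = pd.Series(list(labels), dtype=object)
    if labels.empty:
        raise ValueError("no labels to budget")
    counts = labels.value_counts()
    props = counts.reindex(CATEGORIES, fill_value=0) / counts.sum()
    props.name = "proportion"
    return props
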