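"""Leave-one-subject-out benchmark of eight posture classifiers.

Each subject serves as the held-out test set exactly once; liftings of one
subject therefore never appear on both sides of a fold, which keeps
within-subject correlation from inflating the scores.  For the three
scale-sensitive models (LR, kNN, SVM) a min-max normalization to [0, 1] is
fitted on the training rows of each fold and applied to both sides.

Classifier hyperparameters default to a fixed, externally optimized set
(no search is performed here):

=====  ==============================================================
SVM    polynomial kernel (gamma <u,v> + bias)^power with bias 1.141,
       power 1.734, gamma 1.489
DT     no pruning, minimum 5 records per node
GB     depth-2 trees, 149 boosting rounds, learning rate 0.333
RaF    52 trees, depth 5, minimum node size 4
LR     gradient-descent logistic regression: constant step 0.516,
       at most 111 epochs, tolerance 0.004
kNN    k = 7
MLP    one hidden layer of 5 units, at most 60 iterations
PNN    DDA Parzen network, theta- 0.109, theta+ 0.928
=====  ==============================================================

Seven metrics per fold - accuracy, F-measure, specificity, sensitivity,
precision, recall, AUCROC - are reported as mean +/- SD over the folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .config import CLASSIFIER_NAMES
from .errors import ConfigError, DataError
from .features import FEATURE_COLUMNS
from .pnn import PNNClassifier

__all__ = [
    "ClassifierSpec",
    "FoldMetrics",
    "default_specs",
    "loso_split",
    "minmax_fit_apply",
    "train_predict",
    "compute_metrics",
    "run_benchmark",
    "summarize",
]

log = logging.getLogger(__name__)

METRIC_NAMES = (
    "accuracy", "f_measure", "specificity", "sensitivity",
    "precision", "recall", "aucroc",
)

#: Models that receive per-fold min-max normalization.
SCALED_MODELS = frozenset({"LR", "kNN", "SVM"})


@dataclass(frozen=True)
class ClassifierSpec:
    """A named classifier with its (fixed) hyperparameters."""

    name: str
    params: dict[str, Any] = field(default_factory=dict)

    @property
    def needs_scaling(self) -> bool:
        return self.name in SCALED_MODELS


_DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "SVM": {"bias": 1.141, "power": 1.734, "gamma": 1.489},
    "DT": {"min_samples_split": 5},
    "GB": {"max_depth": 2, "n_estimators": 149, "learning_rate": 0.333},
    "RaF": {"max_depth": 5, "n_estimators": 52, "min_samples_leaf": 4},
    "LR": {"eta0": 0.516, "max_iter": 111, "tol": 0.004},
    "kNN": {"n_neighbors": 7},
    "MLP": {"max_iter": 60, "hidden_layer_sizes": (5,)},
    "PNN": {"theta_minus": 0.109, "theta_plus": 0.928},
}


def default_specs(
    names: tuple[str, ...] = CLASSIFIER_NAMES,
    overrides: dict[str, dict[str, Any]] | None = None,
) -> list[ClassifierSpec]:
    """The benchmark's classifier roster with default hyperparameters."""
    overrides = overrides or {}
    specs = []
    for name in names:
        if name not in _DEFAULT_PARAMS:
            raise ConfigError(f"unknown classifier {name!r}")
        params = dict(_DEFAULT_PARAMS[name])
        params.update(overrides.get(name, {}))
        specs.append(ClassifierSpec(name=name, params=params))
    return specs


def _build_estimator(spec: ClassifierSpec, seed: int):
    p = spec.params
    if spec.name == "SVM":
        bias, power, gamma = p["bias"], p["power"], p["gamma"]

        def poly_kernel(U, V):
            # features are min-max scaled, so the base is positive and a
            # non-integer power is well defined
            return (gamma * (U @ V.T) + bias) ** power

        return SVC(kernel=poly_kernel, C=p.get("C", 1.0), random_state=seed)
    if spec.name == "DT":
        return DecisionTreeClassifier(
            min_samples_split=p["min_samples_split"], random_state=seed
        )
    if spec.name == "GB":
        return GradientBoostingClassifier(
            max_depth=p["max_depth"], n_estimators=p["n_estimators"],
            learning_rate=p["learning_rate"], random_state=seed,
        )
    if spec.name == "RaF":
        return RandomForestClassifier(
            max_depth=p["max_depth"], n_estimators=p["n_estimators"],
            min_samples_leaf=p["min_samples_leaf"], random_state=seed,
        )
    if spec.name == "LR":
        return SGDClassifier(
            loss="log_loss", penalty=None, learning_rate="constant",
            eta0=p["eta0"], max_iter=p["max_iter"], tol=p["tol"],
            random_state=seed,
        )
    if spec.name == "kNN":
        return KNeighborsClassifier(n_neighbors=p["n_neighbors"])
    if spec.name == "MLP":
        return MLPClassifier(
            hidden_layer_sizes=tuple(p["hidden_layer_sizes"]),
            max_iter=p["max_iter"], random_state=seed,
        )
    if spec.name == "PNN":
        return PNNClassifier(
            mode=p.get("mode", "dda"),
            theta_minus=p["theta_minus"], theta_plus=p["theta_plus"],
        )
    raise ConfigError(f"unknown classifier {spec.name!r}")


# ----------------------------------------------------------------------
def loso_split(dataset: pd.DataFrame) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """One (train, test) fold per subject; folds partition the dataset."""
    subjects = sorted(dataset["subject"].unique())
    if len(subjects) < 2:
        raise DataError("LOSO needs at least 2 subjects")
    for sid, grp in dataset.groupby("subject"):
        if grp["label"].nunique() < 2:
            raise DataError(f"subject {sid} has only one class")
    folds = []
    for sid in subjects:
        test = dataset[dataset["subject"] == sid]
        train = dataset[dataset["subject"] != sid]
        folds.append((train, test))
    return folds


def minmax_fit_apply(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Min-max map fitted on TRAIN only, applied to both sides.

    Constant training features map to 0 (with a warning); test values may
    legitimately fall outside [0, 1].
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.size == 0:
        raise DataError("cannot fit min-max scaling on an empty training set")
    lo = train.min(axis=0)
    span = train.max(axis=0) - lo
    flat = span == 0
    if flat.any():
        log.warning("min-max scaling: %d constant training feature(s) mapped to 0",
                    int(flat.sum()))
    span = np.where(flat, 1.0, span)
    return (train - lo) / span, (test - lo) / span


def train_predict(
    spec: ClassifierSpec,
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    seed: int = 0,
    positive_class: str = "unsafe",
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one classifier and score the test rows.

    Returns ``(scores, labels)``: a probability-like score for the positive
    class (decision values are squashed through a logistic when the model
    has no probability output) and the hard predicted label.
    """
    est = _build_estimator(spec, seed)
    with warnings.catch_warnings():
        # MLP's fixed 60-iteration cap routinely stops before full
        # convergence; that cap is part of the benchmarked configuration
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")
        warnings.filterwarnings("ignore", message=".*ConvergenceWarning.*")
        est.fit(train_X, train_y)
        labels = est.predict(test_X)
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(test_X)
            pos_idx = list(est.classes_).index(positive_class)
            scores = proba[:, pos_idx]
        else:
            dec = est.decision_function(test_X)
            # decision_function is oriented toward classes_[1]
            if est.classes_[1] != positive_class:
                dec = -dec
            scores = expit(dec)
    return np.asarray(scores, dtype=float), np.asarray(labels)


# ----------------------------------------------------------------------
@dataclass(frozen=True)
class FoldMetrics:
    """Evaluation of one held-out subject."""

    held_out_subject: int
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    f_measure: float
    specificity: float
    sensitivity: float
    precision: float
    recall: float
    aucroc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "held_out_subject": self.held_out_subject,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            **{m: getattr(self, m) for m in METRIC_NAMES},
        }


def compute_metrics(
    scores: np.ndarray,
    truth: np.ndarray,
    positive_class: str = "unsafe",
    held_out_subject: int = -1,
) -> FoldMetrics:
    """Confusion-matrix metrics at a 0.5 score threshold plus rank AUCROC.

    AUCROC needs both classes in the truth; with a single-class test set it
    is undefined and reported as NaN with a warning (the other metrics are
    still emitted).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.size == 0:
        raise DataError("empty test set")
    pos = truth == positive_class
    pred_pos = scores >= 0.5
    tp = int(np.count_nonzero(pred_pos & pos))
    fp = int(np.count_nonzero(pred_pos & ~pos))
    tn = int(np.count_nonzero(~pred_pos & ~pos))
    fn = int(np.count_nonzero(~pred_pos & pos))

    def _ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    precision = _ratio(tp, tp + fp)
    recall = sensitivity
    f_measure = (
        2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    )
    accuracy = (tp + tn) / scores.size
    if pos.all() or (~pos).all():
        log.warning("single-class test set: AUCROC undefined (subject %s)",
                    held_out_subject)
        auc = float("nan")
    else:
        auc = float(roc_auc_score(pos.astype(int), scores))
    return FoldMetrics(
        held_out_subject=held_out_subject, tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy, f_measure=f_measure, specificity=specificity,
        sensitivity=sensitivity, precision=precision, recall=recall, aucroc=auc,
    )


def run_benchmark(
    dataset: pd.DataFrame,
    specs: list[ClassifierSpec] | None = None,
    seed: int = 0,
    positive_class: str = "unsafe",
    minmax_scope: str = "fold",
) -> pd.DataFrame:
    """LOSO benchmark of every classifier; returns the per-fold metric log.

    ``minmax_scope="fold"`` (default) fits the normalization on each fold's
    training rows only; ``"global"`` fits it once on the whole table before
    splitting, a fidelity mode for platforms that normalize up front.
    """
    specs = specs if specs is not None else default_specs()
    X_all = dataset[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y_all = dataset["label"].to_numpy()
    if minmax_scope == "global":
        X_scaled_all, _ = minmax_fit_apply(X_all, X_all[:0])
    folds = loso_split(dataset)

    records = []
    for spec_i, spec in enumerate(specs):
        for train_df, test_df in folds:
            tr_idx = train_df.index.to_numpy()
            te_idx = test_df.index.to_numpy()
            if spec.needs_scaling:
                if minmax_scope == "global":
                    Xtr, Xte = X_scaled_all[tr_idx], X_scaled_all[te_idx]
                else:
                    Xtr, Xte = minmax_fit_apply(X_all[tr_idx], X_all[te_idx])
            else:
                Xtr, Xte = X_all[tr_idx], X_all[te_idx]
            scores, _ = train_predict(
                spec, Xtr, y_all[tr_idx], Xte,
                seed=seed + 1000 * spec_i, positive_class=positive_class,
            )
            fm = compute_metrics(
                scores, y_all[te_idx], positive_class=positive_class,
                held_out_subject=int(test_df["subject"].iloc[0]),
            )
            records.append({"classifier": spec.name, **fm.as_dict()})
    return pd.DataFrame(records)


def summarize(fold_log: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD (over folds, N-1 denominator) of each metric per classifier."""
    rows = []
    for name, grp in fold_log.groupby("classifier", sort=False):
        row: dict[str, object] = {"classifier": name, "n_folds": len(grp)}
        for m in METRIC_NAMES:
            row[f"{m}_mean"] = grp[m].mean()
            row[f"{m}_std"] = grp[m].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)
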