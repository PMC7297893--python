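"""Train/test classification harness for comparing feature subsets.

Five classifier families cover the usual motor-imagery evaluation spread:
RBF-kernel SVM, random forest, k-nearest-neighbour, a single-hidden-layer
MLP, and L2 logistic regression.  Hyperparameters are fixed, documented
defaults — the claims under test concern the feature-selection layer, not
classifier tuning — and every default can be overridden.

Standardization (z-scoring) and feature selection are always fit on training
rows only; the test table contributes nothing but held-out accuracy.
Each configuration is evaluated ``n_repeats`` times, re-seeding only the
classifier-internal randomness, so deterministic classifiers produce
identical repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import SelectionConfig, select
from .wavelets import FeatureTable

__all__ = ["EvalConfig", "EvalReport", "train_eval", "compare_criteria"]

CLASSIFIERS = ("svm", "random_forest", "knn", "mlp", "logistic_regression")


@dataclass
class EvalConfig:
    """Evaluation settings: classifier family, repeat count, z-scoring flag,
    seed, and optional scikit-learn parameter overrides."""

    classifier: str = "svm"
    n_repeats: int = 5
    standardize: bool = True
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class EvalReport:
    """Per-repeat accuracies with their mean/std, a summed confusion matrix,
    and an echo of the configuration used."""

    accuracies: list[float]
    mean: float
    std: float
    confusion: np.ndarray
    config: EvalConfig
    n_selected: int

    def __post_init__(self) -> None:
        if any(not 0 <= a <= 1 for a in self.accuracies):
            raise ValueError("accuracies must lie in [0, 1]")


def _make_classifier(name: str, seed: int, params: dict):
    if name == "svm":
        kw = dict(kernel="rbf", C=1.0, decision_function_shape="ovr")
    elif name == "random_forest":
        kw = dict(n_estimators=100, random_state=seed)
    elif name == "knn":
        kw = dict(n_neighbors=5)
    elif name == "mlp":
        kw = dict(hidden_layer_sizes=(64,), max_iter=800, random_state=seed)
    elif name == "logistic_regression":
        kw = dict(max_iter=2000)  # L2 regularization is sklearn's default
    kw.update(params)
    cls = {
        "svm": SVC,
        "random_forest": RandomForestClassifier,
        "knn": KNeighborsClassifier,
        "mlp": MLPClassifier,
        "logistic_regression": LogisticRegression,
    }[name]
    return cls(**kw)


def _resolve_selected(table: FeatureTable, selected) -> list[int]:
    if selected is None:
        return list(range(table.n_features))
    idx = []
    for s in selected:
        if isinstance(s, str):
            if s not in table.feature_names:
                raise KeyError(f"unknown feature name {s!r}")
            idx.append(table.feature_names.index(s))
        else:
            if not 0 <= int(s) < table.n_features:
                raise IndexError(f"feature index {s} out of range")
            idx.append(int(s))
    if not idx:
        raise ValueError("selected feature set must not be empty")
    return idx


def train_eval(train: FeatureTable, test: FeatureTable,
               selected: Sequence | None, cfg: EvalConfig | None = None) -> EvalReport:
    """Fit on ``train`` restricted to ``selected`` columns, score on ``test``.

    ``selected`` may hold feature names or column indices; ``None`` means
    all features.  Standardization is fit on training rows only.
    """
    cfg = cfg or EvalConfig()
    if train.feature_names != test.feature_names:
        raise ValueError("train and test tables must share feature names")
    classes = np.unique(train.y)
    missing = set(np.unique(test.y)) - set(classes)
    if missing:
        raise ValueError(f"classes {sorted(missing)} absent from training data")
    idx = _resolve_selected(train, selected)
    Xtr, Xte = train.X[:, idx], test.X[:, idx]
    if cfg.standardize:
        scaler = StandardScaler().fit(Xtr)
        Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
    accs, conf = [], np.zeros((classes.size, classes.size), dtype=np.int64)
    for r in range(cfg.n_repeats):
        clf = _make_classifier(cfg.classifier, cfg.seed + r, cfg.params)
        clf.fit(Xtr, train.y)
        pred = clf.predict(Xte)
        accs.append(float(np.mean(pred == test.y)))
        conf += confusion_matrix(test.y, pred, labels=classes)
    return EvalReport(
        accuracies=accs,
        mean=float(np.mean(accs)),
        std=float(np.std(accs)),
        confusion=conf,
        config=cfg,
        n_selected=len(idx),
    )


def compare_criteria(train: FeatureTable, test: FeatureTable,
                     criteria: Sequence[str] = ("none", "shannon_conditional",
                                                "mutual_info_ranking",
                                                "renyi_min_entropy"),
                     classifiers: Sequence[str] = ("svm",),
                     selection_cfg: SelectionConfig | None = None,
                     eval_cfg: EvalConfig | None = None) -> pd.DataFrame:
    """One evaluation per (selection criterion, classifier family) pair.

    ``"none"`` evaluates all features with no selection.  Selection always
    runs on the training table alone.  Returns a tidy frame with columns
    ``criterion, classifier, n_selected, mean_accuracy, std_accuracy``.
    """
    selection_cfg = selection_cfg or SelectionConfig()
    eval_cfg = eval_cfg or EvalConfig()
    rows = []
    for crit in criteria:
        if crit == "none":
            sel = None
        else:
            res = select(train, replace(selection_cfg, criterion=crit))
            sel = res.selected
        for clf in classifiers:
            rep = train_eval(train, test, sel, replace(eval_cfg, classifier=clf))
            rows.append({
                "criterion": crit,
                "classifier": clf,
                "n_selected": rep.n_selected,
                "mean_accuracy": rep.mean,
                "std_accuracy": rep.std,
            })
    return pd.DataFrame(rows)
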