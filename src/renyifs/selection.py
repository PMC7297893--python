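"""Greedy information-theoretic feature selection.

The core method builds a feature subset ``Q`` one feature at a time:
starting from ``Q^0 = {}``, step ``t`` adds

    f^{t+1} = argmin_{f not in Q^t}  H_inf(C | f, Q^t),

the candidate that minimizes the conditional min-entropy of the class label
``C`` given the already-selected set — equivalently (and verifiably, see
:func:`equivalence_check`) the candidate maximizing the min-entropy mutual
information ``I_inf(C; f | Q^t)``.  Selection stops as soon as the Bayes
risk of guessing the class from the selected subset drops below a tolerance
``epsilon`` (an achieved training accuracy of ``1 - epsilon``), or when
``k_max`` features have been taken.

Two conventional baselines are provided: the same greedy recursion driven by
conditional Shannon entropy, and univariate ranking by Shannon mutual
information (which is blind to feature redundancy and to purely
interaction-borne signal such as an XOR pair).

All criteria are evaluated on the training rows' empirical joint after
equal-frequency binning; the binning is fit once on those rows.  In-sample
Bayes risk is optimistically biased once the conditioning cells become
sparse; an optional stratified two-fold cross-estimate of the risk is
available for the stopping rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .entropy import (
    BinningRule,
    apply_binning,
    fit_binning,
)
from .wavelets import FeatureTable

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "select_renyi",
    "select_shannon",
    "select_mutual_info",
    "select",
    "equivalence_check",
]

CRITERIA = ("renyi_min_entropy", "shannon_conditional", "mutual_info_ranking")


@dataclass
class SelectionConfig:
    """Settings shared by all selection criteria.

    ``epsilon`` is the Bayes-risk stopping tolerance (target training
    accuracy ``1 - epsilon``); ``k_max`` caps the subset size; ties in the
    per-step arg-min/arg-max are broken by the lowest column index.
    """

    criterion: str = "renyi_min_entropy"
    epsilon: float = 0.05
    k_max: int = 16
    binning: BinningRule = field(default_factory=BinningRule)
    cross_validate_risk: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must lie in [0, 1)")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")


@dataclass
class SelectionResult:
    """Ordered selected features with per-step diagnostics.

    ``criterion_trace[t]`` is the winning criterion value at step ``t``;
    ``risk_trace`` holds the Bayes risk of the selected subset after each
    step, starting with the prior risk of the empty set, and is
    non-increasing.  ``subsets`` is the trace of growing index sets.
    """

    selected: list[int]
    selected_names: list[str]
    subsets: list[list[int]]
    criterion_trace: list[float]
    risk_trace: list[float]
    stop_reason: str
    criterion: str

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected indices must be unique")


# ---------------------------------------------------------------------------
# fast empirical conditionals on integer codes
# ---------------------------------------------------------------------------

def _cell_counts(y: np.ndarray, n_classes: int, cells: np.ndarray) -> np.ndarray:
    """Counts matrix (n_cells, n_classes) for integer cell ids ``cells``."""
    _, inv = np.unique(cells, return_inverse=True)
    n_cells = inv.max() + 1
    flat = np.bincount(inv * n_classes + y, minlength=n_cells * n_classes)
    return flat.reshape(n_cells, n_classes).astype(np.float64)


def _h_inf_cond(counts: np.ndarray) -> float:
    """H_inf(C | cells) from a counts matrix."""
    return float(-np.log2(counts.max(axis=1).sum() / counts.sum()))


def _h1_cond(counts: np.ndarray) -> float:
    """H_1(C | cells) from a counts matrix."""
    n = counts.sum()
    tot = counts.sum(axis=1, keepdims=True)
    mask = counts > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log2(np.where(mask, counts, 1.0) / tot)
    return float(-terms[mask].sum() / n)


def _risk(counts: np.ndarray) -> float:
    """In-sample Bayes risk 1 - sum_cells max_class / n."""
    return float(1.0 - counts.max(axis=1).sum() / counts.sum())


def _combine(cells: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Merge a new binned column into existing integer cell ids."""
    return cells * (col.max() + 1) + col


def _cv_risk(y: np.ndarray, n_classes: int, X_sel: np.ndarray,
             rule: BinningRule, seed: int) -> float:
    """Stratified two-fold cross-estimate of the Bayes risk of a subset.

    Bins and plurality votes are fit on one fold and scored on the other;
    cells unseen in training fall back to the training majority class.
    """
    rng = np.random.default_rng(seed)
    folds = np.zeros(y.size, dtype=int)
    for c in range(n_classes):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        folds[idx[: idx.size // 2]] = 1
    errs = []
    for held in (0, 1):
        tr, te = folds != held, folds == held
        fitted = fit_binning(X_sel[tr], rule)
        Ztr = apply_binning(X_sel[tr], fitted)
        Zte = apply_binning(X_sel[te], fitted)
        cells_tr, inv = np.unique(Ztr, axis=0, return_inverse=True)
        counts = np.zeros((cells_tr.shape[0], n_classes))
        np.add.at(counts, (inv, y[tr]), 1.0)
        vote = {tuple(c): int(np.argmax(counts[i]))
                for i, c in enumerate(cells_tr)}
        majority = int(np.bincount(y[tr], minlength=n_classes).argmax())
        pred = np.array([vote.get(tuple(r), majority) for r in Zte])
        errs.append(float(np.mean(pred != y[te])))
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# greedy recursion
# ---------------------------------------------------------------------------

def _validate_table(table: FeatureTable) -> None:
    if np.unique(table.y).size < 2:
        raise ValueError("selection needs at least two classes present")
    if table.n_features < 1:
        raise ValueError("selection needs at least one feature column")
    if all(np.ptp(table.X[:, j]) == 0 for j in range(table.n_features)):
        raise ValueError("all feature columns are constant")


def _greedy(table: FeatureTable, cfg: SelectionConfig,
            crit_fn: Callable[[np.ndarray], float], name: str) -> SelectionResult:
    _validate_table(table)
    y = table.y
    classes, y_idx = np.unique(y, return_inverse=True)
    n_classes = classes.size
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")  # constant noise columns are expected
        rule = fit_binning(table.X, cfg.binning)
    Z = apply_binning(table.X, rule)

    remaining = list(range(table.n_features))
    selected: list[int] = []
    subsets: list[list[int]] = []
    crit_trace: list[float] = []
    cells = np.zeros(y.size, dtype=np.int64)

    def current_risk() -> float:
        if cfg.cross_validate_risk and selected:
            return _cv_risk(y_idx, n_classes, table.X[:, selected], cfg.binning,
                            cfg.seed)
        return _risk(_cell_counts(y_idx, n_classes, cells))

    risk_trace = [current_risk()]
    stop_reason = "no_features_left"
    while True:
        if risk_trace[-1] < cfg.epsilon:
            stop_reason = "risk_below_epsilon"
            break
        if len(selected) >= cfg.k_max:
            stop_reason = "k_max_reached"
            break
        if not remaining:
            stop_reason = "no_features_left"
            break
        best_f, best_v = None, np.inf
        for f in remaining:  # ascending index => lowest-index tie-break
            v = crit_fn(_cell_counts(y_idx, n_classes, _combine(cells, Z[:, f])))
            if v < best_v:  # strict: equal values keep the lowest index
                best_f, best_v = f, v
        cells = _combine(cells, Z[:, best_f])
        selected.append(best_f)
        remaining.remove(best_f)
        subsets.append(list(selected))
        crit_trace.append(best_v)
        risk_trace.append(min(current_risk(), risk_trace[-1]))
    return SelectionResult(
        selected=selected,
        selected_names=[table.feature_names[i] for i in selected],
        subsets=subsets,
        criterion_trace=crit_trace,
        risk_trace=risk_trace,
        stop_reason=stop_reason,
        criterion=name,
    )


def select_renyi(table: FeatureTable, cfg: SelectionConfig | None = None) -> SelectionResult:
    """Greedy forward selection by conditional min-entropy with Bayes-risk
    stopping — the package's core method."""
    cfg = cfg or SelectionConfig()
    return _greedy(table, cfg, _h_inf_cond, "renyi_min_entropy")


def select_shannon(table: FeatureTable, cfg: SelectionConfig | None = None) -> SelectionResult:
    """The identical greedy recursion driven by conditional Shannon entropy
    ``H_1(C | f, Q^t)``, with the same plurality-vote risk stopping rule."""
    cfg = cfg or SelectionConfig()
    return _greedy(table, cfg, _h1_cond, "shannon_conditional")


def select_mutual_info(table: FeatureTable, cfg: SelectionConfig | None = None) -> SelectionResult:
    """Conventional baseline: univariate ranking by Shannon mutual
    information ``I_1(C; f)``, descending, top ``k_max``.

    No conditioning on already-chosen features: duplicated columns score
    identically (redundancy-blind) and interaction-only signal scores near
    zero.
    """
    cfg = cfg or SelectionConfig()
    _validate_table(table)
    classes, y_idx = np.unique(table.y, return_inverse=True)
    n_classes = classes.size
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        rule = fit_binning(table.X, cfg.binning)
    Z = apply_binning(table.X, rule)
    prior = np.bincount(y_idx) / y_idx.size
    h_c = float(-np.sum(prior * np.log2(prior)))
    mi = np.array([h_c - _h1_cond(_cell_counts(y_idx, n_classes, Z[:, f]))
                   for f in range(table.n_features)])
    order = np.argsort(-mi, kind="stable")  # ties -> lowest index first
    selected = [int(i) for i in order[: cfg.k_max]]
    cells = np.zeros(y_idx.size, dtype=np.int64)
    risk_trace = [_risk(_cell_counts(y_idx, n_classes, cells))]
    subsets = []
    for f in selected:
        cells = _combine(cells, Z[:, f])
        subsets.append(selected[: len(subsets) + 1])
        risk_trace.append(min(_risk(_cell_counts(y_idx, n_classes, cells)),
                              risk_trace[-1]))
    return SelectionResult(
        selected=selected,
        selected_names=[table.feature_names[i] for i in selected],
        subsets=subsets,
        criterion_trace=[float(mi[i]) for i in selected],
        risk_trace=risk_trace,
        stop_reason=("no_features_left" if cfg.k_max >= table.n_features
                     else "k_max_reached"),
        criterion="mutual_info_ranking",
    )


def select(table: FeatureTable, cfg: SelectionConfig) -> SelectionResult:
    """Dispatch on ``cfg.criterion``."""
    fn = {
        "renyi_min_entropy": select_renyi,
        "shannon_conditional": select_shannon,
        "mutual_info_ranking": select_mutual_info,
    }[cfg.criterion]
    return fn(table, cfg)


@dataclass
class EquivalenceReport:
    sequences_match: bool
    selected_min_entropy: list[int]
    selected_mi_max: list[int]


def equivalence_check(table: FeatureTable,
                      cfg: SelectionConfig | None = None) -> EquivalenceReport:
    """Verify that minimizing ``H_inf(C|f,Q^t)`` and maximizing
    ``I_inf(C;f|Q^t) = H_inf(C|Q^t) - H_inf(C|f,Q^t)`` pick identical
    sequences under identical tie-breaking."""
    cfg = cfg or SelectionConfig()
    a = _greedy(table, cfg, _h_inf_cond, "renyi_min_entropy")

    # literal I_inf maximization: negate after subtracting the (per-step
    # constant) H_inf(C|Q^t); the constant is folded in by the caller frame
    # via a closure over a mutable holder updated each step.
    _validate_table(table)
    y = table.y
    classes, y_idx = np.unique(y, return_inverse=True)
    n_classes = classes.size
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        rule = fit_binning(table.X, cfg.binning)
    Z = apply_binning(table.X, rule)
    remaining = list(range(table.n_features))
    selected: list[int] = []
    cells = np.zeros(y.size, dtype=np.int64)
    risk = _risk(_cell_counts(y_idx, n_classes, cells))
    while remaining and len(selected) < cfg.k_max and risk >= cfg.epsilon:
        h_q = _h_inf_cond(_cell_counts(y_idx, n_classes, cells)) if selected \
            else float(-np.log2((np.bincount(y_idx) / y_idx.size).max()))
        best_f, best_gain = None, -np.inf
        for f in remaining:
            h_fq = _h_inf_cond(_cell_counts(y_idx, n_classes,
                                            _combine(cells, Z[:, f])))
            gain = h_q - h_fq
            if gain > best_gain:  # strict: equal gains keep the lowest index
                best_f, best_gain = f, gain
        cells = _combine(cells, Z[:, best_f])
        selected.append(best_f)
        remaining.remove(best_f)
        risk = _risk(_cell_counts(y_idx, n_classes, cells))
    return EquivalenceReport(
        sequences_match=(a.selected == selected),
        selected_min_entropy=a.selected,
        selected_mi_max=selected,
    )
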