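"""Discrete entropy, mutual information, and Bayes risk.

All quantities operate on finite discrete distributions estimated from
binned feature columns, and are reported in bits (log base 2; the base only
rescales and never changes any arg-min/arg-max decision downstream).

The one-parameter Renyi family

    H_delta(X) = log2(sum_i p_i**delta) / (1 - delta),   delta > 0, != 1

interpolates between Shannon entropy (delta -> 1) and min-entropy
(delta -> infinity, ``-log2 max_i p_i``).  For a joint p(x, y) the
conditional min-entropy is

    H_inf(X|Y) = -log2 sum_y max_x p(x, y),

which is tied to the Bayes risk — the error probability of the best guess of
X after observing Y — by ``H_inf(X|Y) = -log2(1 - beta(X|Y))``.  The
min-entropy mutual information ``I_inf(X;Y) = H_inf(X) - H_inf(X|Y)`` is
non-negative, zero under independence, and (unlike its Shannon counterpart)
not symmetric.

Continuous features are discretized with a :class:`BinningRule` fit once on
training rows and then applied unchanged, never refit at evaluation time.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "DiscreteDistribution",
    "JointDistribution",
    "BinningRule",
    "fit_binning",
    "apply_binning",
    "estimate_joint",
    "renyi_entropy",
    "shannon_entropy",
    "min_entropy",
    "shannon_conditional_entropy",
    "shannon_mutual_information",
    "conditional_min_entropy",
    "bayes_risk",
    "min_entropy_mutual_information",
]

_MASS_TOL = 1e-12


@dataclass
class DiscreteDistribution:
    """A probability vector over named outcomes."""

    probs: np.ndarray
    outcome_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 1:
            raise ValueError("probs must be a vector")
        if (self.probs < 0).any():
            raise ValueError("negative probability")
        if abs(self.probs.sum() - 1.0) > _MASS_TOL:
            raise ValueError(f"probabilities sum to {self.probs.sum()}, not 1")
        if not self.outcome_labels:
            self.outcome_labels = list(range(self.probs.size))
        elif len(self.outcome_labels) != self.probs.size:
            raise ValueError("one label per outcome required")

    @classmethod
    def from_counts(cls, counts: Sequence[float], labels=None) -> "DiscreteDistribution":
        c = np.asarray(counts, dtype=np.float64)
        return cls(c / c.sum(), list(labels) if labels is not None else [])


@dataclass
class JointDistribution:
    """Joint p(x, y) as a matrix: rows are X outcomes (classes), columns Y
    outcomes (feature cells).  Marginals and conditionals derive from it."""

    probs: np.ndarray
    x_labels: list = field(default_factory=list)
    y_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2:
            raise ValueError("joint probs must be a matrix")
        if (self.probs < 0).any():
            raise ValueError("negative probability")
        if abs(self.probs.sum() - 1.0) > _MASS_TOL:
            raise ValueError(f"joint mass is {self.probs.sum()}, not 1")
        if not self.x_labels:
            self.x_labels = list(range(self.probs.shape[0]))
        if not self.y_labels:
            self.y_labels = list(range(self.probs.shape[1]))
        if (len(self.x_labels), len(self.y_labels)) != self.probs.shape:
            raise ValueError("axis labels must match the joint's shape")

    def marginal_x(self) -> DiscreteDistribution:
        return DiscreteDistribution(self.probs.sum(axis=1) /
                                    self.probs.sum(), list(self.x_labels))

    def marginal_y(self) -> DiscreteDistribution:
        return DiscreteDistribution(self.probs.sum(axis=0) /
                                    self.probs.sum(), list(self.y_labels))

    def swap_axes(self) -> "JointDistribution":
        return JointDistribution(self.probs.T.copy(),
                                 list(self.y_labels), list(self.x_labels))


@dataclass
class BinningRule:
    """Per-feature discretization, fit on training rows only.

    ``equal-frequency`` places bin edges at empirical quantiles (robust to
    the heavy-tailed WPT energy statistics); ``equal-width`` splits the
    observed range evenly.  Values outside the fitted range clip into the
    extreme bins.  After :func:`fit_binning`, ``edges_`` holds one strictly
    increasing interior-edge array per feature.
    """

    strategy: str = "equal-frequency"
    n_bins: int = 8
    edges_: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.strategy not in ("equal-frequency", "equal-width"):
            raise ValueError(f"unknown binning strategy {self.strategy!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")

    @property
    def is_fit(self) -> bool:
        return self.edges_ is not None


def fit_binning(X: np.ndarray, rule: BinningRule | None = None) -> BinningRule:
    """Learn per-feature bin edges from ``X`` (rows = training trials).

    A feature with fewer distinct values than bins keeps only the distinct
    cut points (bins collapse); a constant feature degenerates to a single
    occupied bin and emits a warning.
    """
    rule = rule or BinningRule()
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    edges: list[np.ndarray] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            warnings.warn(f"feature column {j} is constant; single occupied bin")
            edges.append(np.empty(0))
            continue
        if rule.strategy == "equal-frequency":
            qs = np.quantile(col, np.linspace(0, 1, rule.n_bins + 1)[1:-1])
            e = np.unique(qs)
        else:
            e = np.linspace(col.min(), col.max(), rule.n_bins + 1)[1:-1]
        if e.size < rule.n_bins - 1:
            warnings.warn(
                f"feature column {j}: only {e.size + 1} distinct bins "
                f"(requested {rule.n_bins}); bins collapsed"
            )
        edges.append(e)
    return replace(rule, edges_=edges)


def apply_binning(X: np.ndarray, rule: BinningRule) -> np.ndarray:
    """Map values to integer bin indices using the fitted edges."""
    if not rule.is_fit:
        raise ValueError("binning rule is not fit; call fit_binning first")
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != len(rule.edges_):
        raise ValueError(
            f"{X.shape[1]} columns but rule was fit on {len(rule.edges_)}"
        )
    out = np.empty(X.shape, dtype=np.int64)
    for j, e in enumerate(rule.edges_):
        out[:, j] = np.searchsorted(e, X[:, j], side="right")
    return out


def estimate_joint(y: np.ndarray, S: np.ndarray, alpha: float = 0.0,
                   class_labels=None, sparse_warn: bool = True) -> JointDistribution:
    """Empirical joint p(class, cell) from labels and binned columns.

    The Y axis is the Cartesian product of the bin indices of the columns of
    ``S``, restricted to cells that actually occur.  ``alpha`` adds Laplace
    smoothing mass to every retained (class, cell) pair.  A warning is
    emitted when the mean cell occupancy drops below 5 rows: sparse joints
    bias the Bayes risk toward zero, the overfitting mode of in-sample
    greedy selection.
    """
    y = np.asarray(y, dtype=np.int64)
    S = np.atleast_2d(np.asarray(S, dtype=np.int64))
    if S.shape[0] != y.shape[0]:
        raise ValueError(f"{y.shape[0]} labels but {S.shape[0]} binned rows")
    if S.shape[1] < 1:
        raise ValueError("need at least one conditioning column")
    cells, cell_idx = np.unique(S, axis=0, return_inverse=True)
    classes = np.unique(y) if class_labels is None else np.asarray(class_labels)
    class_pos = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((classes.size, cells.shape[0]))
    np.add.at(counts, (np.array([class_pos[c] for c in y]), cell_idx), 1.0)
    if sparse_warn and y.size / cells.shape[0] < 5:
        warnings.warn(
            f"sparse joint: mean cell occupancy "
            f"{y.size / cells.shape[0]:.2f} < 5; Bayes risk will be "
            "optimistically biased"
        )
    counts += alpha
    probs = counts / counts.sum()
    y_labels = [tuple(c) for c in cells]
    return JointDistribution(probs, list(classes), y_labels)


# ---------------------------------------------------------------------------
# entropies
# ---------------------------------------------------------------------------

def renyi_entropy(d: DiscreteDistribution, delta: float) -> float:
    """Renyi entropy of order ``delta`` (> 0, != 1), in bits.

    Uniform over n outcomes gives ``log2 n`` for every order; the family is
    non-increasing in ``delta``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if delta == 1:
        raise ValueError("delta=1 is the Shannon limit; use shannon_entropy")
    p = d.probs[d.probs > 0]
    # evaluate via the max for numerical stability at large delta
    pm = p.max()
    return float(np.log2(pm) * delta / (1 - delta)
                 + np.log2(np.sum((p / pm) ** delta)) / (1 - delta))


def shannon_entropy(d: DiscreteDistribution) -> float:
    """H_1 in bits, with the 0 log 0 := 0 convention."""
    p = d.probs[d.probs > 0]
    return float(-np.sum(p * np.log2(p)))


def min_entropy(d: DiscreteDistribution) -> float:
    """H_inf = -log2 of the most probable outcome."""
    return float(-np.log2(d.probs.max()))


def shannon_conditional_entropy(j: JointDistribution) -> float:
    """H_1(X|Y) = -sum p(x,y) log2 p(x|y) = H_1(X,Y) - H_1(Y)."""
    p = j.probs
    py = p.sum(axis=0)
    mask = p > 0
    cond = p / np.where(py > 0, py, 1.0)[None, :]
    return float(-np.sum(p[mask] * np.log2(cond[mask])))


def shannon_mutual_information(j: JointDistribution) -> float:
    """I_1(X;Y) = H_1(X) + H_1(Y) - H_1(X,Y); symmetric and >= 0."""
    hx = shannon_entropy(j.marginal_x())
    return hx - shannon_conditional_entropy(j)


def conditional_min_entropy(j: JointDistribution) -> float:
    """H_inf(X|Y) = -log2 sum_y max_x p(x,y), in bits."""
    return float(-np.log2(j.probs.max(axis=0).sum()))


def bayes_risk(j: JointDistribution) -> float:
    """beta(X|Y) = 1 - sum_y p(y) max_x p(x|y): the error probability of the
    maximum a-posteriori guess of X given Y.  Lies in [0, 1 - max_x p(x)]."""
    return float(1.0 - j.probs.max(axis=0).sum())


def min_entropy_mutual_information(j: JointDistribution) -> float:
    """I_inf(X;Y) = H_inf(X) - H_inf(X|Y); >= 0, zero under independence,
    not symmetric in its arguments."""
    return min_entropy(j.marginal_x()) - conditional_min_entropy(j)
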