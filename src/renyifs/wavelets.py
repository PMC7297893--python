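"""Wavelet packet decomposition and per-sub-band feature statistics.

A level-``J`` wavelet packet transform (WPT) splits both the approximation
and the detail branch at every level, producing a complete binary tree whose
``2**J`` terminal nodes tile the band ``[0, fs/2]`` into equal-width
sub-bands.  Nodes are indexed ``(j, k)`` with ``0 <= k < 2**j`` in natural
(Paley) order — the order of the recursive split, with children
``(j+1, 2k)`` and ``(j+1, 2k+1)`` — not in ascending centre frequency.

From each terminal node's coefficient vector four scalar statistics are
computed (energy, population variance, standard deviation, waveform length),
so a level-5 decomposition yields ``32 * 4 = 128`` features per channel.
Multichannel epochs concatenate channels, channel-major.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pywt

from .preprocessing import EpochSet

__all__ = [
    "WPTConfig",
    "WPTNode",
    "FeatureTable",
    "wpt_decompose",
    "node_statistics",
    "extract_features",
]

FEATURE_STATS = ("energy", "variance", "std", "waveform_length")


@dataclass
class WPTConfig:
    """Decomposition settings.

    ``level`` must not exceed ``log2`` of the signal length.  The wavelet
    must be orthogonal (Daubechies "db4" by default), so terminal-node
    energies sum to the signal energy when the length is compatible with the
    boundary mode.  ``boundary_mode="periodization"`` keeps the transform
    exactly orthogonal; other PyWavelets modes pad and are only approximately
    energy-preserving.
    """

    level: int = 5
    wavelet: str = "db4"
    boundary_mode: str = "periodization"
    features: tuple[str, ...] = FEATURE_STATS

    def __post_init__(self) -> None:
        if self.level < 1:
            raise ValueError("level must be >= 1")
        w = pywt.Wavelet(self.wavelet)
        if not w.orthogonal:
            raise ValueError(f"wavelet {self.wavelet!r} is not orthogonal")
        bad = [f for f in self.features if f not in FEATURE_STATS]
        if bad:
            raise ValueError(f"unknown feature statistics: {bad}")
        if not self.features:
            raise ValueError("at least one feature statistic required")


@dataclass
class WPTNode:
    """One sub-band space of the packet tree: level ``j``, index ``k``."""

    level: int
    index: int
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        if not 0 <= self.index < 2 ** self.level:
            raise ValueError(f"node index {self.index} invalid at level {self.level}")

    @property
    def children(self) -> tuple[tuple[int, int], tuple[int, int]]:
        j, k = self.level, self.index
        return (j + 1, 2 * k), (j + 1, 2 * k + 1)


@dataclass
class FeatureTable:
    """Trials-by-features matrix with class labels — the currency passed
    between feature extraction, selection, and classification."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (trials x features)")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("rows of X must match length of y")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("columns of X must match feature_names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not self.class_names:
            self.class_names = [str(c) for c in range(int(self.y.max(initial=-1)) + 1)]

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["label"] = self.y
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        if "label" not in df.columns:
            raise ValueError(f"{path}: missing 'label' column")
        y = df.pop("label").to_numpy(dtype=np.int64)
        return cls(df.to_numpy(dtype=np.float64), y, list(df.columns))


def wpt_decompose(signal: np.ndarray, cfg: WPTConfig) -> list[WPTNode]:
    """Decompose a 1-D signal into its ``2**level`` terminal packet nodes.

    Nodes are returned in natural (Paley) order, ``k = 0 .. 2**level - 1``.
    The decomposition is invertible: reconstructing from all terminal nodes
    recovers the signal to numerical precision.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    n = signal.shape[0]
    if n < 2 ** cfg.level or cfg.level > math.floor(math.log2(n)):
        raise ValueError(
            f"level {cfg.level} too deep for signal of {n} samples "
            f"(need level <= log2(n))"
        )
    wp = pywt.WaveletPacket(signal, cfg.wavelet, mode=cfg.boundary_mode,
                            maxlevel=cfg.level)
    nodes = wp.get_level(cfg.level, order="natural")
    return [WPTNode(cfg.level, k, np.asarray(nd.data, dtype=np.float64))
            for k, nd in enumerate(nodes)]


def wpt_reconstruct(nodes: Sequence[WPTNode], cfg: WPTConfig,
                    n_samples: int) -> np.ndarray:
    """Inverse transform from a full set of terminal nodes."""
    wp = pywt.WaveletPacket(None, cfg.wavelet, mode=cfg.boundary_mode,
                            maxlevel=cfg.level)
    for nd in nodes:
        path = "".join("a" if (nd.index >> (nd.level - 1 - b)) & 1 == 0 else "d"
                       for b in range(nd.level))
        wp[path] = nd.coefficients
    return np.asarray(wp.reconstruct(update=False))[:n_samples]


def node_statistics(coeffs: np.ndarray,
                    features: Sequence[str] = FEATURE_STATS) -> np.ndarray:
    """Scalar statistics of one coefficient vector, in the requested order.

    energy ``sum(c**2)``; variance is the population variance (divide by n);
    std its square root; waveform length ``sum(|c[i] - c[i-1]|)``.
    """
    c = np.asarray(coeffs, dtype=np.float64)
    if c.size == 0:
        raise ValueError("empty coefficient vector")
    out = []
    for f in features:
        if f == "energy":
            out.append(float(np.sum(c * c)))
        elif f == "variance":
            out.append(float(np.var(c)))
        elif f == "std":
            out.append(float(np.std(c)))
        elif f == "waveform_length":
            out.append(float(np.sum(np.abs(np.diff(c)))))
        else:
            raise ValueError(f"unknown statistic {f!r}")
    return np.asarray(out)


def extract_features(epochs: EpochSet, cfg: WPTConfig | None = None) -> FeatureTable:
    """WPT features for every epoch: channels processed independently and
    concatenated channel-major, then node ``k``, then statistic.

    Column count is ``n_channels * 2**level * len(features)``; names follow
    ``ch<i>.j<level>.k<k>.<stat>``.  Extraction is deterministic.
    """
    cfg = cfg or WPTConfig()
    n_ep, n_ch, n_samp = epochs.data.shape
    if n_samp < 2 ** cfg.level:
        raise ValueError(
            f"epochs of {n_samp} samples too short for level {cfg.level}"
        )
    n_nodes = 2 ** cfg.level
    n_stats = len(cfg.features)
    names = [
        f"ch{i}.j{cfg.level}.k{k}.{stat}"
        for i in range(n_ch)
        for k in range(n_nodes)
        for stat in cfg.features
    ]
    X = np.empty((n_ep, n_ch * n_nodes * n_stats))
    for e in range(n_ep):
        col = 0
        for i in range(n_ch):
            for nd in wpt_decompose(epochs.data[e, i], cfg):
                X[e, col:col + n_stats] = node_statistics(nd.coefficients, cfg.features)
                col += n_stats
    return FeatureTable(X, epochs.labels.copy(), names,
                        [str(c) for c in range(epochs.n_classes)])
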