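"""Synthetic data: EEG-like sessions and planted feature tables.

Two generators make the whole pipeline testable without any recorded data.

``generate_session`` emulates a cue-paced four-class motor-imagery session:
6 runs of 12 trials per class per run (288 trials, 72 per class).  Each
class expresses band-limited oscillatory power (narrow-band filtered noise)
on a class-specific pair of channels during the imagery window of its
trials, superposed on 1/f-like broadband background noise on every channel.
The signal model is deliberately simple — no volume conduction, no ERD/ERS
dynamics, no ocular artifacts — but it makes wavelet-packet sub-band
energies the truly discriminative statistics, exercising the real feature
pathway end to end.  Ground truth records which channel x band carries each
class.

``generate_planted_table`` skips the signal layer and emits a labelled
feature table directly, with planted structure: informative columns with
class-dependent mean shifts (standardized effect size ``d``), optional
redundant near-copies, an optional XOR pair whose members are marginally
independent of the binary label, and pure-noise columns.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical specs give bit-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .io import EventSchedule, Recording
from .wavelets import FeatureTable

__all__ = [
    "SessionSpec",
    "PlantedTableSpec",
    "generate_session",
    "generate_planted_table",
]

#: class -> list of (channel, centre Hz, bandwidth Hz, RMS amplitude in uV).
#: Each class activates a disjoint channel pair in a distinct narrow band,
#: all below the 50 Hz Nyquist of the 100 Hz analysis rate.
DEFAULT_BAND_PROFILES: dict[int, list[tuple[int, float, float, float]]] = {
    0: [(0, 8.0, 2.0, 20.0), (1, 8.0, 2.0, 20.0)],
    1: [(2, 14.0, 2.0, 20.0), (3, 14.0, 2.0, 20.0)],
    2: [(4, 20.0, 2.0, 20.0), (5, 20.0, 2.0, 20.0)],
    3: [(6, 26.0, 2.0, 20.0), (7, 26.0, 2.0, 20.0)],
}


@dataclass
class SessionSpec:
    """Shape and signal model of one synthetic session.

    Defaults reproduce the standard four-class cue-paced paradigm: 6 runs,
    12 trials per class per run, 250 Hz acquisition, 10 channels.  The
    imagery window (``mi_window_s``, seconds relative to trial onset) is
    when the class band profile is active; ``noise_sd`` is the RMS of the
    1/f-like background in microvolts.
    """

    n_classes: int = 4
    runs_per_session: int = 6
    trials_per_run_per_class: int = 12
    fs: float = 250.0
    trial_length_s: float = 6.0
    inter_trial_gap_s: float = 1.0
    n_channels: int = 10
    class_band_profiles: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_BAND_PROFILES.items()})
    mi_window_s: tuple[float, float] = (3.0, 6.0)
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_classes", "runs_per_session", "trials_per_run_per_class",
                     "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.trial_length_s <= 0 or self.inter_trial_gap_s < 0:
            raise ValueError("trial length must be positive, gap non-negative")
        for cls, profiles in self.class_band_profiles.items():
            for ch, centre, bw, _gain in profiles:
                if not 0 < centre < self.fs / 2:
                    raise ValueError(
                        f"class {cls}: band centre {centre} Hz outside (0, Nyquist)")
                if ch >= self.n_channels:
                    raise ValueError(f"class {cls}: channel {ch} out of range")

    @property
    def n_trials(self) -> int:
        return (self.n_classes * self.runs_per_session
                * self.trials_per_run_per_class)


def _pink_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """1/f-amplitude noise (flat below 1 Hz), scaled to RMS ``sd``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec /= np.sqrt(np.maximum(f, 1.0))
    x = np.fft.irfft(spec, n)
    return x * (sd / np.std(x))


def _band_burst(rng: np.random.Generator, n: int, fs: float,
                centre: float, bw: float, rms: float) -> np.ndarray:
    """Narrow-band filtered noise with a Tukey on/off envelope."""
    low = max(centre - bw / 2, 0.1)
    high = min(centre + bw / 2, fs / 2 * 0.99)
    sos = sps.butter(4, (low, high), btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n + 200))[100:-100]
    x *= sps.windows.tukey(n, 0.2)
    s = np.std(x)
    return x * (rms / s) if s > 0 else x


def generate_session(spec: SessionSpec | None = None
                     ) -> tuple[Recording, EventSchedule, dict]:
    """One synthetic session: recording, event schedule, and ground truth.

    Trials are laid out sequentially (onset spacing ``trial_length + gap``);
    within each run the 12-per-class trial order is shuffled.  Returns the
    default paradigm's 288 events, 72 per class.
    """
    spec = spec or SessionSpec()
    ss = np.random.SeedSequence(spec.seed)
    rng_sched, rng_noise, rng_trials = [np.random.default_rng(s)
                                        for s in ss.spawn(3)]
    fs = spec.fs
    spacing = int(round((spec.trial_length_s + spec.inter_trial_gap_s) * fs))
    n_trials = spec.n_trials
    n_samples = spacing * n_trials + int(fs)  # one second of tail

    # schedule: per run, a shuffled block of trials_per_run_per_class of each class
    labels = []
    for _run in range(spec.runs_per_session):
        block = np.repeat(np.arange(spec.n_classes), spec.trials_per_run_per_class)
        rng_sched.shuffle(block)
        labels.extend(int(c) for c in block)
    onsets = [i * spacing for i in range(n_trials)]
    schedule = EventSchedule(list(zip(onsets, labels)), spec.n_classes)

    data = np.empty((spec.n_channels, n_samples))
    for ch in range(spec.n_channels):
        data[ch] = _pink_noise(rng_noise, n_samples, fs, spec.noise_sd) \
            if spec.noise_sd > 0 else np.zeros(n_samples)

    w0, w1 = spec.mi_window_s
    burst_len = int(round((w1 - w0) * fs))
    trial_rngs = [np.random.default_rng(s) for s in
                  np.random.SeedSequence((spec.seed, 1)).spawn(n_trials)]
    for i, (onset, cls) in enumerate(schedule.events):
        a = onset + int(round(w0 * fs))
        for ch, centre, bw, gain in spec.class_band_profiles.get(cls, []):
            data[ch, a:a + burst_len] += _band_burst(
                trial_rngs[i], burst_len, fs, centre, bw, gain)

    rec = Recording(
        data=data,
        fs=fs,
        channel_labels=[f"C{i}" for i in range(spec.n_channels)],
        meta={"generator": "renyifs.synthetic.generate_session", "seed": spec.seed},
    )
    truth = {
        "class_profiles": {c: list(p) for c, p in spec.class_band_profiles.items()},
        "mi_window_s": spec.mi_window_s,
        "labels": list(schedule.class_ids),
    }
    return rec, schedule, truth


@dataclass
class PlantedTableSpec:
    """Labelled feature table with known informative structure.

    Informative column ``j`` (the j-th entry of ``informative_idx``) shifts
    the mean of class ``j mod n_classes`` by ``effect_size`` standard
    deviations, so each informative column flags one class against the rest
    and all of them together are needed to separate every class.  Redundant
    columns are informative columns plus N(0, ``jitter_sd``) jitter.  With
    ``xor_pair`` the table is a two-class problem: columns 0 and 1 are
    fair Bernoulli draws and the label is their XOR, so each member is
    marginally independent of the label; the remaining columns are noise
    drawn from ``noise_distribution`` ("normal" or "bernoulli").
    """

    n_trials_per_class: int = 100
    n_features: int = 50
    n_classes: int = 4
    informative_idx: tuple[int, ...] = (0, 1, 2)
    effect_size: float = 3.0
    redundant_copies: int = 0
    xor_pair: bool = False
    noise_distribution: str = "normal"
    jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_distribution not in ("normal", "bernoulli"):
            raise ValueError(f"unknown noise distribution {self.noise_distribution!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        needed = (2 if self.xor_pair
                  else len(self.informative_idx) + self.redundant_copies)
        if self.n_features < needed:
            raise ValueError(
                f"n_features={self.n_features} cannot host {needed} structured columns")
        if not self.xor_pair:
            for i in self.informative_idx:
                if not 0 <= i < self.n_features:
                    raise ValueError(f"informative index {i} out of range")


def _noise(rng: np.random.Generator, shape, kind: str) -> np.ndarray:
    if kind == "bernoulli":
        return rng.integers(0, 2, size=shape).astype(np.float64)
    return rng.standard_normal(shape)


def generate_planted_table(spec: PlantedTableSpec | None = None
                           ) -> tuple[FeatureTable, dict]:
    """Feature table plus ground truth listing the planted column indices."""
    spec = spec or PlantedTableSpec()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    if spec.xor_pair:
        n = 2 * spec.n_trials_per_class
        X = _noise(rng, (n, spec.n_features), spec.noise_distribution)
        f1 = rng.integers(0, 2, size=n)
        f2 = rng.integers(0, 2, size=n)
        X[:, 0] = f1
        X[:, 1] = f2
        y = (f1 ^ f2).astype(np.int64)
        truth = {"xor_pair": (0, 1), "informative": (0, 1), "redundant": ()}
        names = [f"f{j:03d}" for j in range(spec.n_features)]
        return FeatureTable(X, y, names, ["0", "1"]), truth

    n = spec.n_classes * spec.n_trials_per_class
    y = np.repeat(np.arange(spec.n_classes), spec.n_trials_per_class)
    rng.shuffle(y)
    X = _noise(rng, (n, spec.n_features), spec.noise_distribution)
    for j, col in enumerate(spec.informative_idx):
        target = j % spec.n_classes
        X[y == target, col] += spec.effect_size
    free = [j for j in range(spec.n_features) if j not in spec.informative_idx]
    redundant = []
    for r in range(spec.redundant_copies):
        src = spec.informative_idx[r % len(spec.informative_idx)]
        dst = free[r]
        X[:, dst] = X[:, src] + rng.normal(0, spec.jitter_sd, size=n)
        redundant.append(dst)
    truth = {
        "informative": tuple(spec.informative_idx),
        "redundant": tuple(redundant),
        "scheme": "column j elevates class j mod n_classes by effect_size",
    }
    names = [f"f{j:03d}" for j in range(spec.n_features)]
    classes = [str(c) for c in range(spec.n_classes)]
    return FeatureTable(X, y, names, classes), truth
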