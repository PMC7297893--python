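"""Reading and writing of EEG recordings and trial event schedules.

Two on-disk dialects are supported for multichannel signals:

* a plain-text delimited matrix (one channel per row, tab separated) with a
  two-line header carrying the sampling rate and channel labels — lossless;
* EDF (European Data Format), the field's standard 16-bit exchange format —
  quantized to the per-channel physical range, worst-case absolute error of
  ``span / 2**15`` where ``span`` is the channel's peak-to-peak amplitude.

Event schedules are tab-separated tables with columns ``onset_sample`` and
``class_id``.  Sample indices are 0-based throughout; amplitudes are assumed
to be in microvolts and are never rescaled.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "EventSchedule",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
]


@dataclass
class Recording:
    """A multichannel signal block.

    Parameters
    ----------
    data
        Real matrix of shape ``(n_channels, n_samples)``, in microvolts.
    fs
        Sampling rate in Hz, strictly positive.
    channel_labels
        One label per row of ``data``.
    meta
        Free-form annotations carried along but never interpreted.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.data.shape[0] < 1:
            raise ValueError("a Recording needs at least one channel")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{self.data.shape[0]} channels but "
                f"{len(self.channel_labels)} labels"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        bad = ~np.isfinite(self.data)
        if bad.any():
            ch, samp = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite sample at channel {ch} "
                f"({self.channel_labels[ch]!r}), sample {samp}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.fs


@dataclass
class EventSchedule:
    """Trial onsets and class labels for one session.

    ``events`` is a list of ``(onset_sample, class_id)`` pairs with strictly
    increasing onsets; every ``class_id`` lies in ``{0, ..., n_classes-1}``.
    """

    events: list[tuple[int, int]]
    n_classes: int

    def __post_init__(self) -> None:
        self.events = [(int(o), int(c)) for o, c in self.events]
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        onsets = [o for o, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        for i, (o, c) in enumerate(self.events):
            if o < 0:
                raise ValueError(f"event {i}: negative onset {o}")
            if not 0 <= c < self.n_classes:
                raise ValueError(
                    f"event {i}: class_id {c} outside 0..{self.n_classes - 1}"
                )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([o for o, _ in self.events], dtype=np.int64)

    @property
    def class_ids(self) -> np.ndarray:
        return np.array([c for _, c in self.events], dtype=np.int64)

    def rescale(self, factor: float) -> "EventSchedule":
        """Map onsets onto a new sampling grid (e.g. after resampling).

        ``factor`` is ``new_fs / old_fs``; onsets are rounded to the nearest
        sample of the new grid.
        """
        ev = [(int(round(o * factor)), c) for o, c in self.events]
        return EventSchedule(ev, self.n_classes)


# ---------------------------------------------------------------------------
# delimited-matrix dialect
# ---------------------------------------------------------------------------

def _write_delimited(rec: Recording, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#fs={rec.fs!r}\n")
        fh.write("#channels=" + ",".join(rec.channel_labels) + "\n")
        for row in rec.data:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def _read_delimited(path: Path) -> Recording:
    fs = None
    channels = None
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#fs="):
                fs = float(line[4:])
            elif line.startswith("#channels="):
                channels = line[len("#channels="):].split(",")
            elif line.startswith("#"):
                continue
            else:
                rows.append([float(v) for v in line.split("\t")])
    if fs is None:
        raise ValueError(f"{path}: missing '#fs=' header line")
    if channels is None:
        raise ValueError(f"{path}: missing '#channels=' header line")
    data = np.asarray(rows, dtype=np.float64)
    return Recording(data=data, fs=fs, channel_labels=channels)


# ---------------------------------------------------------------------------
# EDF dialect (16-bit).  Writing is done directly against the EDF field
# layout; reading goes through MNE.
# ---------------------------------------------------------------------------

def _fit8(value: float) -> str:
    """Format a float into at most 8 ASCII characters (an EDF header field)."""
    for prec in (7, 6, 5, 4, 3, 2, 1):
        s = f"{value:.{prec}g}"
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot format {value} in 8 characters")


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _write_edf(rec: Recording, path: Path) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF output requires an integer sampling rate")
    spr = int(round(fs))  # one-second data records
    if rec.n_samples % spr != 0:
        raise ValueError(
            "EDF output requires a whole number of 1-s records: "
            f"{rec.n_samples} samples at fs={spr}"
        )
    n_records = rec.n_samples // spr
    ns = rec.n_channels

    # symmetric physical range, rounded up so the stored 8-char header value
    # re-parses to a range that still covers the data
    phys = np.empty(ns)
    for i in range(ns):
        peak = float(np.max(np.abs(rec.data[i])))
        peak = peak if peak > 0 else 1.0
        p = float(_fit8(peak * 1.0001))
        while p < peak:
            p = float(_fit8(p * 1.001))
        phys[i] = p

    header = bytearray()
    header += _pad("0", 8)
    header += _pad("synthetic", 80)
    header += _pad("renyifs export", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (ns + 1)), 8)
    header += _pad("", 44)
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)
    header += _pad(str(ns), 4)
    for lab in rec.channel_labels:
        header += _pad(lab, 16)
    header += b" " * (80 * ns)                       # transducer
    for _ in range(ns):
        header += _pad("uV", 8)
    for i in range(ns):
        header += _pad(_fit8(-phys[i]), 8)
    for i in range(ns):
        header += _pad(_fit8(phys[i]), 8)
    for _ in range(ns):
        header += _pad("-32768", 8)
    for _ in range(ns):
        header += _pad("32767", 8)
    header += b" " * (80 * ns)                       # prefiltering
    for _ in range(ns):
        header += _pad(str(spr), 8)
    header += b" " * (32 * ns)

    scale = 32767.0 / phys                            # digital per microvolt
    digital = np.round(rec.data * scale[:, None]).astype(np.int16)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(struct.pack(f"<{ns * spr}h", *block.ravel()))


def _read_edf(path: Path) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6                      # MNE works in volts
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        meta={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

_FORMATS = ("edf", "delimited")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    return "edf" if path.suffix.lower() == ".edf" else "delimited"


def read_recording(path, format: str | None = None) -> Recording:
    """Read a :class:`Recording` from ``path``.

    ``format`` is ``"edf"`` or ``"delimited"``; when omitted it is inferred
    from the file suffix (``.edf`` means EDF, anything else delimited).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    return _read_edf(path) if fmt == "edf" else _read_delimited(path)


def write_recording(rec: Recording, path, format: str | None = None) -> None:
    """Write ``rec`` to ``path`` in the chosen (or suffix-inferred) format."""
    if not isinstance(rec, Recording):
        raise TypeError("rec must be a Recording")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _write_edf(rec, path)
    else:
        _write_delimited(rec, path)


def read_events(path) -> EventSchedule:
    """Read an :class:`EventSchedule` from a TSV with columns
    ``onset_sample`` and ``class_id``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("onset_sample", "class_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    events = list(zip(df["onset_sample"].astype(int), df["class_id"].astype(int)))
    n_classes = int(df["class_id"].max()) + 1 if len(df) else 0
    if "n_classes" in df.attrs:
        n_classes = int(df.attrs["n_classes"])
    return EventSchedule(events=events, n_classes=max(n_classes, 1))


def write_events(schedule: EventSchedule, path) -> None:
    df = pd.DataFrame(schedule.events, columns=["onset_sample", "class_id"])
    df.to_csv(path, sep="\t", index=False)
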