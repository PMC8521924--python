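"""Epoch containers and EEG input/output.

Defines the three containers the rest of the pipeline consumes — a
continuous :class:`Recording`, a single :class:`Epoch`, and the central
:class:`EpochSet` (epochs x channels x samples at a shared sampling
rate, with condition labels and artifact annotations) — together with
EDF reading, event-locked segmentation, resampling, zero-phase
filtering, and a single-file HDF5 store.

Conventions used throughout the package:

* amplitudes are in microvolts (EDF physical units are converted on read);
* sample indexing is 0-based and all intervals are half-open ``[start, end)``;
* every transform preserves epoch order, labels, and artifact flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np
from scipy import signal

STORE_VERSION = "1"

__all__ = [
    "Recording",
    "Epoch",
    "EpochSet",
    "FormatError",
    "StoreVersionError",
    "read_edf",
    "epoch_continuous",
    "resample",
    "bandpass_filter",
    "save_store",
    "load_store",
    "export_annotations",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class StoreVersionError(ValueError):
    """Raised when an epoch store was written by an incompatible version."""


@dataclass
class Recording:
    """Continuous multichannel EEG with event marks.

    ``signals`` is (n_channels, n_samples) in microvolts; ``events`` is a
    list of ``(sample_index, label)`` pairs with indices in
    ``[0, n_samples)``.
    """

    signals: np.ndarray
    fs: float
    channel_names: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = self.signals.shape[1]
        for idx, _ in self.events:
            if not 0 <= idx < n:
                raise ValueError(f"event sample {idx} outside [0, {n})")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


@dataclass
class Epoch:
    """One trial: a (channels x samples) array plus its annotations."""

    data: np.ndarray
    fs: float
    label: str | None = None
    artifact_flag: bool | None = None
    subject_id: str = "s0"

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


class EpochSet:
    """Homogeneous ordered collection of epochs.

    Backed by one (n_epochs, n_channels, n_samples) float array so the
    whole set can be handed to vectorised feature extraction.  Order is
    stable and preserved by every transform in the package.
    """

    def __init__(
        self,
        data: np.ndarray,
        fs: float,
        channel_names: Sequence[str] | None = None,
        labels: Sequence[str | None] | None = None,
        artifact_flags: Sequence[bool | None] | None = None,
        subject_ids: Sequence[str] | None = None,
        metadata: dict | None = None,
    ) -> None:
        data = np.asarray(data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        if not np.all(np.isfinite(data)):
            raise ValueError("epoch data must be finite")
        if fs <= 0:
            raise ValueError("sampling rate must be positive")
        n, c, _ = data.shape
        self.data = data
        self.fs = float(fs)
        self.channel_names = (
            list(channel_names) if channel_names is not None else [f"ch{i}" for i in range(c)]
        )
        if len(self.channel_names) != c:
            raise ValueError("channel_names length mismatch")
        self.labels = list(labels) if labels is not None else [None] * n
        self.artifact_flags = (
            list(artifact_flags) if artifact_flags is not None else [None] * n
        )
        self.subject_ids = list(subject_ids) if subject_ids is not None else ["s0"] * n
        for name, seq in (
            ("labels", self.labels),
            ("artifact_flags", self.artifact_flags),
            ("subject_ids", self.subject_ids),
        ):
            if len(seq) != n:
                raise ValueError(f"{name} length mismatch")
        self.metadata: dict = dict(metadata) if metadata else {}

    # -- basic protocol ------------------------------------------------
    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def __len__(self) -> int:
        return self.n_epochs

    def __getitem__(self, i: int) -> Epoch:
        return Epoch(
            data=self.data[i],
            fs=self.fs,
            label=self.labels[i],
            artifact_flag=self.artifact_flags[i],
            subject_id=self.subject_ids[i],
        )

    def __iter__(self) -> Iterator[Epoch]:
        for i in range(self.n_epochs):
            yield self[i]

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(),
            self.fs,
            list(self.channel_names),
            list(self.labels),
            list(self.artifact_flags),
            list(self.subject_ids),
            dict(self.metadata),
        )

    def select(self, indices: Sequence[int]) -> "EpochSet":
        idx = list(indices)
        return EpochSet(
            self.data[idx],
            self.fs,
            list(self.channel_names),
            [self.labels[i] for i in idx],
            [self.artifact_flags[i] for i in idx],
            [self.subject_ids[i] for i in idx],
            dict(self.metadata),
        )


# ---------------------------------------------------------------------
# EDF reading
# ---------------------------------------------------------------------

def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording` (microvolts).

    The annotations channel, if present, is mapped to ``(sample, label)``
    events.  Raises :class:`FormatError` on unreadable or truncated files.
    """
    import mne

    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no branch - mne raises various types
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc
    # mne returns SI volts; the package-wide unit is microvolts
    signals = raw.get_data() * 1e6
    fs = float(raw.info["sfreq"])
    events = []
    for ann in raw.annotations:
        idx = int(round(ann["onset"] * fs))
        if 0 <= idx < signals.shape[1]:
            events.append((idx, str(ann["description"])))
    return Recording(signals=signals, fs=fs, channel_names=list(raw.ch_names), events=events)


# ---------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------

def epoch_continuous(
    rec: Recording,
    event_label: str,
    t_before: float,
    t_after: float,
    subject_id: str = "s0",
) -> EpochSet:
    """Cut event-locked epochs ``[event - t_before*fs, event + t_after*fs)``.

    Events whose window does not fit inside the recording are dropped and
    counted in ``metadata['dropped_count']``.  Raises ``ValueError`` when
    no event carries ``event_label``.
    """
    if t_before + t_after <= 0:
        raise ValueError("epoch window must have positive length")
    matches = [idx for idx, lab in rec.events if lab == event_label]
    if not matches:
        raise ValueError(f"no events labelled {event_label!r}")
    before = int(round(t_before * rec.fs))
    after = int(round(t_after * rec.fs))
    windows = []
    dropped = 0
    for idx in matches:
        start, end = idx - before, idx + after
        if start < 0 or end > rec.n_samples:
            dropped += 1
            continue
        windows.append(rec.signals[:, start:end])
    if not windows:
        raise ValueError("all matching events fell outside the recording")
    data = np.stack(windows)
    return EpochSet(
        data,
        rec.fs,
        rec.channel_names,
        labels=[event_label] * len(windows),
        subject_ids=[subject_id] * len(windows),
        metadata={"dropped_count": dropped, "event_label": event_label},
    )


# ---------------------------------------------------------------------
# Resampling and filtering
# ---------------------------------------------------------------------

def resample(es: EpochSet, target_fs: float) -> EpochSet:
    """Polyphase-resample every epoch to ``target_fs``.

    New epoch length is ``round(n * target_fs / fs)``; labels, flags and
    order are preserved.  Upsampling is allowed but emits a warning.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs > es.fs:
        warnings.warn("upsampling beyond the original rate", stacklevel=2)
    if target_fs == es.fs:
        return es.copy()
    frac = (Fraction(target_fs).limit_denominator(10**6) / Fraction(es.fs).limit_denominator(10**6)).limit_denominator(10**4)
    up, down = frac.numerator, frac.denominator
    n_out = int(round(es.n_samples * target_fs / es.fs))
    out = signal.resample_poly(es.data, up, down, axis=2)
    if out.shape[2] > n_out:
        out = out[:, :, :n_out]
    elif out.shape[2] < n_out:  # pragma: no cover - pad for awkward ratios
        out = np.pad(out, ((0, 0), (0, 0), (0, n_out - out.shape[2])), mode="edge")
    res = EpochSet(
        out, target_fs, es.channel_names, es.labels, es.artifact_flags, es.subject_ids, es.metadata
    )
    return res


def bandpass_filter(es: EpochSet, lo: float, hi: float, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass (``lo=0`` means low-pass)."""
    nyq = es.fs / 2.0
    if lo < 0 or hi <= lo:
        raise ValueError("need 0 <= lo < hi")
    if hi >= nyq:
        raise ValueError(f"hi={hi} Hz must be below Nyquist ({nyq} Hz)")
    if lo == 0:
        sos = signal.butter(order, hi, btype="lowpass", fs=es.fs, output="sos")
    else:
        sos = signal.butter(order, [lo, hi], btype="bandpass", fs=es.fs, output="sos")
    out = signal.sosfiltfilt(sos, es.data, axis=2)
    return EpochSet(
        out, es.fs, es.channel_names, es.labels, es.artifact_flags, es.subject_ids, es.metadata
    )


# ---------------------------------------------------------------------
# Single-file HDF5 store
# ---------------------------------------------------------------------
# Layout: /data (epochs x channels x samples, float64), /fs, /channels,
# /labels ("" encodes null), /artifact_flags (int8; -1 null), /subject_ids;
# root attribute "store_version".

def save_store(es: EpochSet, path: str | Path) -> Path:
    path = Path(path)
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.attrs["store_version"] = STORE_VERSION
        f.create_dataset("data", data=es.data)
        f.create_dataset("fs", data=es.fs)
        f.create_dataset("channels", data=np.array(es.channel_names, dtype=object), dtype=str_dt)
        labels = np.array(["" if l is None else str(l) for l in es.labels], dtype=object)
        f.create_dataset("labels", data=labels, dtype=str_dt)
        flags = np.array(
            [-1 if fl is None else int(bool(fl)) for fl in es.artifact_flags], dtype=np.int8
        )
        f.create_dataset("artifact_flags", data=flags)
        f.create_dataset(
            "subject_ids", data=np.array(es.subject_ids, dtype=object), dtype=str_dt
        )
    return path


def load_store(path: str | Path) -> EpochSet:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            version = f.attrs.get("store_version")
            if version != STORE_VERSION:
                raise StoreVersionError(
                    f"store version mismatch: found {version!r}, expected {STORE_VERSION!r}"
                )
            data = f["data"][()]
            fs = float(f["fs"][()])
            channels = [c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]]
            raw_labels = [
                l.decode() if isinstance(l, bytes) else str(l) for l in f["labels"][()]
            ]
            labels = [None if l == "" else l for l in raw_labels]
            flags = [None if v == -1 else bool(v) for v in f["artifact_flags"][()]]
            subjects = [
                s.decode() if isinstance(s, bytes) else str(s) for s in f["subject_ids"][()]
            ]
    except OSError as exc:
        raise FormatError(f"cannot read epoch store {path}: {exc}") from exc
    return EpochSet(data, fs, channels, labels, flags, subjects)


def export_annotations(es: EpochSet, path: str | Path) -> Path:
    """Write (epoch_index, subject_id, label, artifact_flag) as CSV."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame(
        {
            "epoch_index": np.arange(es.n_epochs),
            "subject_id": es.subject_ids,
            "label": ["" if l is None else l for l in es.labels],
            "artifact_flag": ["" if f is None else int(f) for f in es.artifact_flags],
        }
    ).to_csv(path, index=False)
    return path
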