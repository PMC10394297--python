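"""EEG input, normalization, windowing and labelling.

Recordings enter either as EDF files (read through :mod:`mne`) or as
in-memory arrays.  Each recording is min-max normalized per channel, cut
into overlapping fixed-length windows (1 s / 250 samples with 50 % overlap
by default), and every window is labelled seizure/normal by the majority
state of the samples it covers, using TUH-style interval annotations
(CSV columns ``patient_id, start_s, stop_s, label`` with labels ``seiz`` /
``bckg``).

Windows are half-open ``[start, start + window_len)`` with 0-based start
indices.  Channel order is preserved from the file header; no re-montaging
or filtering is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyBatchError,
    LabelingError,
    MissingChannelError,
    UnsupportedFormatError,
    ValidationError,
)

__all__ = [
    "MultichannelSignal",
    "EEGSegment",
    "SegmentBatch",
    "read_edf_recording",
    "write_edf_recording",
    "minmax_normalize",
    "segment_signal",
    "label_segments",
    "annotation_to_mask",
    "read_annotations_csv",
    "write_annotations_csv",
    "save_segment_batch",
    "load_segment_batch",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class MultichannelSignal:
    """A raw multichannel recording, ``samples`` in µV, shape [channels, time]."""

    samples: np.ndarray
    sampling_rate_hz: float
    channel_names: list[str]
    patient_id: str = "unknown"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be 2-D [channels, time]")
        if self.samples.shape[0] < 1 or self.samples.shape[1] < 1:
            raise ValidationError("need at least one channel and one sample")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling rate must be positive")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValidationError("channel_names length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class EEGSegment:
    """One normalized window with its labels."""

    samples: np.ndarray  # [channels, window_len], values in [0, 1]
    category_label: int | None
    patient_label: int | None
    segment_index: int


@dataclass
class SegmentBatch:
    """A stack of equally shaped segments, stored as dense arrays.

    ``category_labels``/``patient_labels`` are ``None`` until
    :func:`label_segments` attaches them.
    """

    samples: np.ndarray  # [N, channels, window_len]
    segment_indices: np.ndarray  # [N]
    category_labels: np.ndarray | None = None  # [N] in {0, 1}
    patient_labels: np.ndarray | None = None  # [N] integer patient index
    channel_names: list[str] = field(default_factory=list)
    sampling_rate_hz: float = 250.0
    hop: int | None = None  # sample hop between consecutive segment starts

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 3:
            raise ValidationError("batch samples must be [N, channels, window_len]")
        if self.samples.shape[0] < 1:
            raise EmptyBatchError("batch must contain at least one segment")
        if len(self.segment_indices) != self.samples.shape[0]:
            raise ValidationError("segment_indices length mismatch")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        for i in range(self.n):
            yield EEGSegment(
                samples=self.samples[i],
                category_label=None if self.category_labels is None else int(self.category_labels[i]),
                patient_label=None if self.patient_labels is None else int(self.patient_labels[i]),
                segment_index=int(self.segment_indices[i]),
            )


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------


def _edf_header_sample_counts(path: Path) -> list[int]:
    """Peek at per-signal samples-per-record in the EDF header."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        ns = int(header[252:256].decode("ascii").strip())
        per_signal = fh.read(ns * 256)
    off = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    counts = []
    for i in range(ns):
        raw = per_signal[off + i * 8 : off + (i + 1) * 8]
        counts.append(int(raw.decode("ascii").strip()))
    return counts


def read_edf_recording(
    path: str | Path,
    channels: Sequence[str] | None = None,
    patient_id: str | None = None,
) -> MultichannelSignal:
    """Read an EDF file into a :class:`MultichannelSignal` (samples in µV).

    ``channels`` selects and orders a subset of channels by name; all
    selected channels must share one sampling rate.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    counts = _edf_header_sample_counts(path)
    if len(set(counts)) > 1:
        raise UnsupportedFormatError(
            f"mixed per-channel sampling rates in {path.name}: {sorted(set(counts))}"
        )
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channels is not None:
        missing = [c for c in channels if c not in raw.ch_names]
        if missing:
            raise MissingChannelError(f"channels not in recording: {missing}")
        picks = list(channels)
    else:
        picks = raw.ch_names
    data = raw.get_data(picks=picks) * 1e6  # mne returns volts for EEG channels
    return MultichannelSignal(
        samples=data,
        sampling_rate_hz=float(raw.info["sfreq"]),
        channel_names=list(picks),
        patient_id=patient_id if patient_id is not None else path.stem,
    )


def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _phys_field(value: float) -> str:
    """Most precise representation of a physical limit that fits 8 chars."""
    for digits in range(7, 0, -1):
        s = f"{value:.{digits}g}"
        if len(s) <= 8:
            return s
    return f"{value:.0e}"


def write_edf_recording(signal: MultichannelSignal, path: str | Path) -> Path:
    """Write a 16-bit EDF file.

    Minimal EDF writer (no installed library exports EDF); 1-second data
    records when the length divides evenly, otherwise a single record
    spanning the recording.  Physical dimension is µV.
    """
    path = Path(path)
    x = signal.samples
    nchan, nsamp = x.shape
    fs = signal.sampling_rate_hz
    if abs(fs - round(fs)) < 1e-9 and nsamp % int(round(fs)) == 0:
        spr = int(round(fs))
        n_records = nsamp // spr
        record_dur = 1.0
    else:
        spr = nsamp
        n_records = 1
        record_dur = nsamp / fs

    scale = np.maximum(np.abs(x).max(axis=1), 1e-6) / 32767.0
    digital = np.clip(np.round(x / scale[:, None]), -32768, 32767).astype("<i2")
    # physical limits chosen so the EDF slope/offset reproduce dig*scale
    phys_lo = -32768.0 * scale
    phys_hi = 32767.0 * scale

    header = b"".join(
        [
            _ascii_field("0", 8),
            _ascii_field(signal.patient_id, 80),
            _ascii_field("seizdg synthetic recording", 80),
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (nchan + 1), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(f"{record_dur:g}", 8),
            _ascii_field(nchan, 4),
        ]
    )
    fields = [
        [_ascii_field(name, 16) for name in signal.channel_names],
        [_ascii_field("", 80)] * nchan,
        [_ascii_field("uV", 8)] * nchan,
        [_ascii_field(_phys_field(m), 8) for m in phys_lo],
        [_ascii_field(_phys_field(m), 8) for m in phys_hi],
        [_ascii_field("-32768", 8)] * nchan,
        [_ascii_field("32767", 8)] * nchan,
        [_ascii_field("", 80)] * nchan,
        [_ascii_field(spr, 8)] * nchan,
        [_ascii_field("", 32)] * nchan,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for fld in fields:
            fh.write(b"".join(fld))
        for r in range(n_records):
            for c in range(nchan):
                fh.write(digital[c, r * spr : (r + 1) * spr].tobytes())
    return path


# ---------------------------------------------------------------------------
# Normalization and segmentation
# ---------------------------------------------------------------------------


def minmax_normalize(x: MultichannelSignal | np.ndarray):
    """Per-channel min-max scaling into [0, 1].

    Constant channels map to all-zeros.  Applied per recording, before
    segmentation, so adjacent overlapping windows stay consistent.
    """
    if isinstance(x, MultichannelSignal):
        return MultichannelSignal(
            samples=minmax_normalize(x.samples),
            sampling_rate_hz=x.sampling_rate_hz,
            channel_names=list(x.channel_names),
            patient_id=x.patient_id,
        )
    arr = np.asarray(x, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValidationError("input contains NaN or Inf")
    lo = arr.min(axis=-1, keepdims=True)
    hi = arr.max(axis=-1, keepdims=True)
    span = hi - lo
    out = np.where(span > 0, (arr - lo) / np.where(span > 0, span, 1.0), 0.0)
    return out


def segment_signal(
    x: MultichannelSignal,
    window_len: int = 250,
    overlap_fraction: float = 0.5,
) -> SegmentBatch:
    """Cut a recording into overlapping windows.

    hop = window_len * (1 - overlap_fraction); the trailing remainder
    shorter than one window is dropped.
    """
    if not (0 <= overlap_fraction < 1):
        raise ValidationError("overlap_fraction must be in [0, 1)")
    t = x.n_samples
    if t < window_len:
        raise EmptyBatchError(f"signal length {t} shorter than window {window_len}")
    hop = int(round(window_len * (1.0 - overlap_fraction)))
    if hop < 1:
        raise ValidationError("hop smaller than one sample")
    n_seg = (t - window_len) // hop + 1
    starts = np.arange(n_seg) * hop
    windows = np.stack([x.samples[:, s : s + window_len] for s in starts])
    return SegmentBatch(
        samples=windows,
        segment_indices=np.arange(n_seg),
        channel_names=list(x.channel_names),
        sampling_rate_hz=x.sampling_rate_hz,
        hop=hop,
    )


def annotation_to_mask(
    annotation: pd.DataFrame | Iterable[tuple],
    n_samples: int,
    sampling_rate_hz: float,
) -> np.ndarray:
    """Expand interval annotations into a per-sample mask.

    Returns int8 mask with 1 = seizure, 0 = normal, -1 = not annotated.
    Intervals are [start_s, stop_s) in seconds; labels ``seiz``/``bckg``
    (or 1/0).
    """
    mask = np.full(n_samples, -1, dtype=np.int8)
    if isinstance(annotation, pd.DataFrame):
        rows = annotation[["start_s", "stop_s", "label"]].itertuples(index=False)
    else:
        rows = annotation
    for start_s, stop_s, label in rows:
        a = int(round(start_s * sampling_rate_hz))
        b = int(round(stop_s * sampling_rate_hz))
        if isinstance(label, str):
            value = 1 if label.strip().lower() == "seiz" else 0
        else:
            value = int(label)
        mask[max(a, 0) : min(b, n_samples)] = value
    return mask


def label_segments(
    batch: SegmentBatch,
    annotation,
    patient_label: int,
) -> SegmentBatch:
    """Attach category and patient labels to a segment batch.

    ``annotation`` is a per-sample mask (1 = seizure, 0 = normal, -1 = gap;
    see :func:`annotation_to_mask` for building one from interval tables).
    Each window is labelled by the majority state of the samples it covers;
    a window overlapping an annotation gap raises :class:`LabelingError`.
    """
    window_len = batch.samples.shape[2]
    hop = batch.hop if batch.hop is not None else window_len // 2
    mask = np.asarray(annotation)
    if mask.dtype == object or mask.ndim != 1:
        raise ValidationError("annotation mask must be a 1-D numeric array")
    labels = np.empty(batch.n, dtype=np.int64)
    for i, seg_idx in enumerate(batch.segment_indices):
        start = int(seg_idx) * hop
        window = mask[start : start + window_len]
        if len(window) < window_len or (window < 0).any():
            raise LabelingError(f"annotation gap overlaps window at segment {seg_idx}")
        labels[i] = 1 if window.mean() > 0.5 else 0
    return SegmentBatch(
        samples=batch.samples,
        segment_indices=batch.segment_indices,
        category_labels=labels,
        patient_labels=np.full(batch.n, patient_label, dtype=np.int64),
        channel_names=list(batch.channel_names),
        sampling_rate_hz=batch.sampling_rate_hz,
        hop=batch.hop,
    )


# ---------------------------------------------------------------------------
# Annotation CSV and batch serialization
# ---------------------------------------------------------------------------


def read_annotations_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "start_s", "stop_s", "label"}
    if not required.issubset(df.columns):
        raise ValidationError(f"annotation CSV must have columns {sorted(required)}")
    return df


def write_annotations_csv(rows: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    rows.to_csv(path, index=False)
    return path


def save_segment_batch(batch: SegmentBatch, prefix: str | Path) -> tuple[Path, Path]:
    """Serialize a batch as ``<prefix>.npz`` plus a JSON sidecar."""
    prefix = Path(prefix)
    npz = prefix.with_suffix(".npz")
    meta = prefix.with_suffix(".json")
    arrays = {"samples": batch.samples, "segment_indices": batch.segment_indices}
    if batch.category_labels is not None:
        arrays["category_labels"] = batch.category_labels
    if batch.patient_labels is not None:
        arrays["patient_labels"] = batch.patient_labels
    np.savez_compressed(npz, **arrays)
    meta.write_text(
        json.dumps(
            {
                "channel_names": batch.channel_names,
                "sampling_rate_hz": batch.sampling_rate_hz,
                "hop": batch.hop,
                "n_segments": int(batch.n),
                "labeled": batch.category_labels is not None,
            },
            indent=2,
        )
    )
    return npz, meta


def load_segment_batch(prefix: str | Path) -> SegmentBatch:
    prefix = Path(prefix)
    with np.load(prefix.with_suffix(".npz")) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return SegmentBatch(
        samples=arrays["samples"],
        segment_indices=arrays["segment_indices"],
        category_labels=arrays.get("category_labels"),
        patient_labels=arrays.get("patient_labels"),
        channel_names=meta["channel_names"],
        sampling_rate_hz=meta["sampling_rate_hz"],
        hop=meta.get("hop"),
    )
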