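"""Windowing of recordings and per-window binary labeling.

Records are segmented into fixed-length windows (default 11 s with 10 s
overlap, i.e. a 1 s stride) and each window inherits a binary apnea label
from either annotation dialect: explicit event intervals (by overlap fraction
or window-center membership) or minute labels (the label of the minute
containing the window's center sample).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .records import (
    Channel,
    Dialect,
    SignalRecord,
    minute_labels_from_events,
    read_text_record,
)

__all__ = [
    "LabelRule",
    "SegmentationConfig",
    "WindowSet",
    "segment_record",
    "label_windows",
    "read_record",
]


class LabelRule(str, enum.Enum):
    CENTER_IN_EVENT = "CENTER_IN_EVENT"
    MIN_OVERLAP_FRACTION = "MIN_OVERLAP_FRACTION"


class RecordFormat(str, enum.Enum):
    TEXT = "TEXT"
    WFDB = "WFDB"


@dataclass
class SegmentationConfig:
    window_s: float = 11.0
    overlap_s: float = 10.0
    label_rule: LabelRule = LabelRule.MIN_OVERLAP_FRACTION
    min_overlap: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_s < self.window_s:
            raise ValueError(
                f"overlap ({self.overlap_s} s) must satisfy 0 <= overlap < window ({self.window_s} s)"
            )
        if not 0.0 <= self.min_overlap <= 1.0:
            raise ValueError("min_overlap must lie in [0, 1]")
        self.label_rule = LabelRule(self.label_rule)

    @property
    def stride_s(self) -> float:
        return self.window_s - self.overlap_s


@dataclass
class WindowSet:
    """Aligned fixed-length windows with labels and provenance."""

    windows: np.ndarray  # (n_windows, window_samples)
    labels: np.ndarray  # (n_windows,) in {0, 1}
    fs: float
    source_ids: list[str]
    start_times_s: np.ndarray  # (n_windows,)
    channel: Channel | None = None

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.start_times_s = np.asarray(self.start_times_s, dtype=float)
        if self.channel is not None:
            self.channel = Channel(self.channel)
        n = self.windows.shape[0]
        if not (len(self.labels) == len(self.source_ids) == len(self.start_times_s) == n):
            raise ValueError("windows, labels, source_ids and start_times_s must agree in length")
        if n and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def window_samples(self) -> int:
        return self.windows.shape[1]

    def take(self, indices: Sequence[int] | np.ndarray) -> "WindowSet":
        idx = np.asarray(indices, dtype=int)
        return WindowSet(
            self.windows[idx],
            self.labels[idx],
            self.fs,
            [self.source_ids[i] for i in idx],
            self.start_times_s[idx],
            self.channel,
        )

    def replace(self, **kwargs) -> "WindowSet":
        return replace(self, **kwargs)

    def pair_keys(self) -> list[tuple[str, int]]:
        """Hashable (source, start-time-in-ms) keys used to align modalities."""
        return [
            (sid, int(round(t * 1000.0)))
            for sid, t in zip(self.source_ids, self.start_times_s)
        ]


def segment_record(record: SignalRecord, cfg: SegmentationConfig | None = None) -> WindowSet:
    """Cut a record into overlapping windows; trailing partial windows are dropped."""
    cfg = cfg or SegmentationConfig()
    ws = int(round(cfg.window_s * record.fs))
    ss = int(round(cfg.stride_s * record.fs))
    if ss < 1:
        raise ValueError(f"stride of {cfg.stride_s} s is below one sample at fs={record.fs}")
    n_samples = record.samples.size
    if n_samples < ws:
        raise ValueError(
            f"record of {record.duration_s:.3f} s is shorter than one window; "
            f"at least {cfg.window_s} s required"
        )
    n_windows = (n_samples - ws) // ss + 1
    starts = np.arange(n_windows) * ss
    idx = starts[:, None] + np.arange(ws)[None, :]
    windows = record.samples[idx]
    wset = WindowSet(
        windows=windows,
        labels=np.zeros(n_windows, dtype=np.int8),
        fs=record.fs,
        source_ids=[record.record_id] * n_windows,
        start_times_s=starts / record.fs,
        channel=record.channel,
    )
    return label_windows(wset, record.events, record.annotation_dialect, cfg)


def label_windows(
    wset: WindowSet,
    events: Sequence[tuple[float, float]],
    dialect: Dialect,
    cfg: SegmentationConfig | None = None,
) -> WindowSet:
    """Assign binary labels to windows from either annotation dialect."""
    cfg = cfg or SegmentationConfig()
    dialect = Dialect(dialect)
    window_s = wset.window_samples / wset.fs
    labels = np.zeros(len(wset), dtype=np.int8)
    if dialect is Dialect.EVENT_INTERVALS:
        for i, t0 in enumerate(wset.start_times_s):
            t1 = t0 + window_s
            if cfg.label_rule is LabelRule.CENTER_IN_EVENT:
                center = t0 + window_s / 2.0
                labels[i] = int(any(o <= center < o + d for o, d in events))
            else:
                overlap = sum(max(0.0, min(t1, o + d) - max(t0, o)) for o, d in events)
                labels[i] = int(overlap >= cfg.min_overlap * window_s)
    elif dialect is Dialect.MINUTE_LABELS:
        duration = max((t + window_s for t in wset.start_times_s), default=0.0)
        minute_labels = minute_labels_from_events(events, duration)
        for i, t0 in enumerate(wset.start_times_s):
            minute = int((t0 + window_s / 2.0) // 60.0)
            if minute < len(minute_labels):
                labels[i] = minute_labels[minute]
    else:  # pragma: no cover - Dialect() above rejects unknown values
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return wset.replace(labels=labels)


def read_record(path: str | Path, fmt: RecordFormat | str = RecordFormat.TEXT) -> SignalRecord:
    """Read a recording in the delimited-text dialect or a WFDB record.

    WFDB support requires the optional ``wfdb`` package; the plain-text
    dialect is the ground-truth format and round-trips exactly with
    :func:`apneafusion.records.write_record`.
    """
    fmt = RecordFormat(fmt)
    if fmt is RecordFormat.TEXT:
        return read_text_record(path)
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise RuntimeError(
            "reading WFDB records requires the optional 'wfdb' package; "
            "install it or convert to the text dialect"
        ) from exc
    rec = wfdb.rdrecord(str(path))  # pragma: no cover
    sig = rec.p_signal[:, 0]  # pragma: no cover
    name = (rec.sig_name[0] or "").upper()  # pragma: no cover
    channel = Channel.SPO2 if "SP" in name else Channel.ECG  # pragma: no cover
    return SignalRecord(sig, float(rec.fs), channel, [], Dialect.EVENT_INTERVALS,
                        record_id=Path(path).stem)  # pragma: no cover
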