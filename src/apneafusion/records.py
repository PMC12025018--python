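"""Single-channel physiological recordings and their plain-text serialization.

A :class:`SignalRecord` holds one channel's samples together with the apnea
event intervals and the annotation dialect the source used.  Two dialects are
supported: explicit event intervals (onset + duration, as in event-scored
polysomnograms) and per-minute binary labels (as in minute-scored Holter-style
databases).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Channel",
    "Dialect",
    "SignalRecord",
    "minute_labels_from_events",
    "events_from_minute_labels",
    "write_record",
    "read_text_record",
]


class Channel(str, enum.Enum):
    ECG = "ECG"
    SPO2 = "SPO2"


class Dialect(str, enum.Enum):
    EVENT_INTERVALS = "EVENT_INTERVALS"
    MINUTE_LABELS = "MINUTE_LABELS"


#: minimum seconds of event overlap for a minute to be scored apneic
MINUTE_OVERLAP_S = 5.0


def _validate_events(events: Sequence[tuple[float, float]], duration: float) -> list[tuple[float, float]]:
    out = [(float(o), float(d)) for o, d in events]
    prev_end = -math.inf
    for onset, dur in out:
        if dur <= 0:
            raise ValueError(f"event duration must be positive, got {dur}")
        if onset < prev_end:
            raise ValueError(f"events overlap or are unsorted near onset {onset} s")
        if onset < 0 or onset + dur > duration + 1e-9:
            raise ValueError(
                f"event [{onset}, {onset + dur}) s falls outside the record of {duration} s"
            )
        prev_end = onset + dur
    return out


@dataclass
class SignalRecord:
    """One channel's samples plus annotation intervals.

    Events are half-open ``[onset, onset + duration)`` intervals in seconds,
    sorted and non-overlapping.  SpO2 samples are percentages in [0, 100].
    """

    samples: np.ndarray
    fs: float
    channel: Channel
    events: list[tuple[float, float]] = field(default_factory=list)
    annotation_dialect: Dialect = Dialect.EVENT_INTERVALS
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D vector")
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        self.channel = Channel(self.channel)
        self.annotation_dialect = Dialect(self.annotation_dialect)
        self.events = _validate_events(self.events, self.duration_s)
        if self.channel is Channel.SPO2 and self.samples.size:
            lo, hi = float(self.samples.min()), float(self.samples.max())
            if lo < 0.0 or hi > 100.0:
                raise ValueError(f"SpO2 samples must lie in [0, 100], got range [{lo}, {hi}]")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


def minute_labels_from_events(
    events: Sequence[tuple[float, float]],
    duration_s: float,
    min_overlap_s: float = MINUTE_OVERLAP_S,
) -> np.ndarray:
    """Score each whole minute apneic when events overlap it by >= ``min_overlap_s``."""
    n_minutes = int(math.ceil(duration_s / 60.0))
    labels = np.zeros(n_minutes, dtype=np.int8)
    for m in range(n_minutes):
        lo, hi = 60.0 * m, min(60.0 * (m + 1), duration_s)
        overlap = 0.0
        for onset, dur in events:
            overlap += max(0.0, min(hi, onset + dur) - max(lo, onset))
        if overlap >= min_overlap_s:
            labels[m] = 1
    return labels


def events_from_minute_labels(labels: np.ndarray, duration_s: float) -> list[tuple[float, float]]:
    """Merge runs of apneic minutes back into event intervals."""
    events: list[tuple[float, float]] = []
    start = None
    for m, lab in enumerate(labels):
        if lab and start is None:
            start = 60.0 * m
        elif not lab and start is not None:
            events.append((start, 60.0 * m - start))
            start = None
    if start is not None:
        events.append((start, min(60.0 * len(labels), duration_s) - start))
    return events


def _annotation_path(record_path: Path) -> Path:
    return record_path.with_suffix(record_path.suffix + ".ann")


def write_record(record: SignalRecord, path: str | Path) -> Path:
    """Write one sample per line with a ``#``-header, plus a sidecar annotation file.

    EVENT_INTERVALS sidecars hold ``onset<TAB>duration`` rows; MINUTE_LABELS
    sidecars hold ``minute<TAB>label`` rows derived from the event list.
    """
    path = Path(path)
    header = [
        f"# fs {record.fs!r}",
        f"# channel {record.channel.value}",
        f"# dialect {record.annotation_dialect.value}",
        f"# id {record.record_id}",
    ]
    body = "\n".join(repr(float(v)) for v in record.samples)
    path.write_text("\n".join(header) + "\n" + body + "\n")

    ann = _annotation_path(path)
    if record.annotation_dialect is Dialect.EVENT_INTERVALS:
        lines = [f"{float(onset)!r}\t{float(dur)!r}" for onset, dur in record.events]
    else:
        labels = minute_labels_from_events(record.events, record.duration_s)
        lines = [f"{m}\t{int(lab)}" for m, lab in enumerate(labels)]
    ann.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_text_record(path: str | Path) -> SignalRecord:
    """Read a record written by :func:`write_record`; exact round-trip.

    Raises ``ValueError`` with the offending line number for malformed
    annotation rows, and for empty files or a non-positive sampling rate.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty record file")
    fs = None
    channel = None
    dialect = Dialect.EVENT_INTERVALS
    record_id = ""
    samples: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line[1:].split(None, 1)
            if len(parts) < 1:
                continue
            key = parts[0]
            val = parts[1].strip() if len(parts) > 1 else ""
            if key == "fs":
                fs = float(val)
            elif key == "channel":
                channel = Channel(val)
            elif key == "dialect":
                dialect = Dialect(val)
            elif key == "id":
                record_id = val
            continue
        try:
            samples.append(float(line))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed sample line {line!r}") from exc
    if fs is None or channel is None:
        raise ValueError(f"{path}: missing required '# fs' or '# channel' header")
    if fs <= 0:
        raise ValueError(f"{path}: sampling frequency must be positive, got {fs}")
    if not samples:
        raise ValueError(f"{path}: record contains no samples")

    arr = np.asarray(samples, dtype=float)
    duration = arr.size / fs
    events: list[tuple[float, float]] = []
    ann = _annotation_path(path)
    if ann.exists():
        if dialect is Dialect.EVENT_INTERVALS:
            for lineno, line in enumerate(ann.read_text().splitlines(), start=1):
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{ann}:{lineno}: expected 'onset<TAB>duration', got {line!r}")
                try:
                    events.append((float(fields[0]), float(fields[1])))
                except ValueError as exc:
                    raise ValueError(f"{ann}:{lineno}: non-numeric annotation {line!r}") from exc
        else:
            labels = []
            for lineno, line in enumerate(ann.read_text().splitlines(), start=1):
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) != 2 or fields[1] not in ("0", "1"):
                    raise ValueError(f"{ann}:{lineno}: expected 'minute<TAB>0|1', got {line!r}")
                labels.append(int(fields[1]))
            events = events_from_minute_labels(np.asarray(labels, dtype=np.int8), duration)
    return SignalRecord(
        samples=arr, fs=fs, channel=channel, events=events,
        annotation_dialect=dialect, record_id=record_id,
    )


def copy_with(record: SignalRecord, **kwargs) -> SignalRecord:
    return replace(record, **kwargs)
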