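"""Sensor pipeline: raw timestamped records -> deduplicated column-per-sensor
table -> forward-filled table -> overlapping max-windows -> window labels.

Raw input is either JSON-lines records ``{"t_ms": ..., "sensor": ...,
"value": ...}`` or an equivalent long-format table. Annotation tracks are
``(start time ms, label s-expression)`` pairs.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from causact.errors import CausactError, ParseError

__all__ = [
    "SensorTable",
    "WindowedTable",
    "AnnotationTrack",
    "read_records",
    "read_wide_csv",
    "deduplicate",
    "forward_fill",
    "window",
    "align_annotation",
]

UNKNOWN_LABEL = "(unknown)"


@dataclass
class SensorTable:
    """Wide table: strictly increasing ``t_ms`` index, one column per sensor.

    ``measured`` is a boolean frame of the same shape marking cells that
    came from an actual record (as opposed to fill)."""

    data: pd.DataFrame
    measured: pd.DataFrame

    def __post_init__(self):
        ts = self.data.index.to_numpy()
        if len(ts) > 1 and not (np.diff(ts) > 0).all():
            raise CausactError("timestamps must be strictly increasing")

    @property
    def sensors(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class WindowedTable:
    """Per-window summarised sensor values plus the raw spans they cover."""

    data: pd.DataFrame  # index: window number; columns: sensors
    spans: list[tuple[int, int]]  # (first row position, last row position)
    timestamps: np.ndarray  # raw t_ms column the spans refer to
    size: int
    overlap: float

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class AnnotationTrack:
    """(start time ms, label) pairs; times must be non-decreasing."""

    entries: list[tuple[int, str]]
    schema: tuple[str, ...] | None = None  # allowed action names

    def __post_init__(self):
        times = [t for t, _ in self.entries]
        if any(b < a for a, b in zip(times, times[1:])):
            raise CausactError("annotation times must be non-decreasing")
        if self.schema is not None:
            for _, label in self.entries:
                name = label.strip("() ").split()[0] if label.strip("() ") else ""
                if name not in self.schema:
                    raise ParseError(f"annotation label {label!r} outside the action schema")

    @classmethod
    def from_csv(cls, path, schema=None) -> "AnnotationTrack":
        df = pd.read_csv(path)
        return cls(entries=[(int(t), str(l)) for t, l in zip(df["t_ms"], df["label"])], schema=schema)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["t_ms", "label"])

    def label_at(self, t_ms: float) -> str:
        """Label active at a raw timestamp; (unknown) before the first entry."""
        out = UNKNOWN_LABEL
        for start, label in self.entries:
            if start <= t_ms:
                out = label
            else:
                break
        return out


def read_wide_csv(path) -> SensorTable:
    """Load an already column-per-sensor CSV with a ``t_ms`` column."""
    df = pd.read_csv(path)
    if "t_ms" not in df.columns:
        raise ParseError("wide CSV must have a 't_ms' column")
    df = df.set_index("t_ms")
    return SensorTable(data=df, measured=df.notna())


def read_records(source) -> list[dict]:
    """Load raw records from a JSON-lines file path/handle or pass through an
    iterable of dicts."""
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        fh = open(source) if isinstance(source, (str, bytes)) else source
        with fh:
            return [json.loads(line) for line in fh if line.strip()]
    return list(source)


def deduplicate(records: Iterable[Mapping], sensors: Sequence[str] | None = None) -> SensorTable:
    """Merge rows sharing a timestamp into one row per timestamp.

    Two records for the same (timestamp, sensor) with the same value
    collapse silently; with different values the last one wins and a
    warning is emitted (documented rule).
    """
    cells: dict[int, dict[str, float]] = {}
    seen_sensors: list[str] = []
    for rec in records:
        try:
            t = int(rec["t_ms"])
            s = str(rec["sensor"])
            v = float(rec["value"])
        except (KeyError, TypeError, ValueError) as e:
            raise ParseError(f"unparseable record {rec!r}: {e}")
        if s not in seen_sensors:
            seen_sensors.append(s)
        row = cells.setdefault(t, {})
        if s in row and row[s] != v:
            warnings.warn(
                f"conflicting values for sensor {s!r} at t={t}: "
                f"{row[s]} -> {v} (last write wins)"
            )
        row[s] = v
    cols = list(sensors) if sensors is not None else seen_sensors
    times = sorted(cells)
    data = pd.DataFrame(
        [[cells[t].get(s, np.nan) for s in cols] for t in times],
        index=pd.Index(times, name="t_ms"),
        columns=cols,
    )
    return SensorTable(data=data, measured=data.notna())


def forward_fill(
    table: SensorTable, defaults: Mapping[str, float] | None = None
) -> SensorTable:
    """Replace undefined cells with the nearest previous value per sensor.

    Leading undefined cells take the sensor's declared default. A sensor
    with no values at all and no default is an error. Measured cells are
    never changed.
    """
    defaults = dict(defaults or {})
    data = table.data.ffill()
    for s in data.columns:
        if data[s].isna().any():
            if s in defaults:
                data[s] = data[s].fillna(defaults[s])
            elif table.data[s].isna().all():
                raise CausactError(f"sensor {s!r} has no values and no default")
            else:
                raise CausactError(f"sensor {s!r} has leading undefined cells and no default")
    return SensorTable(data=data, measured=table.measured.copy())


def window(
    table: SensorTable, w: int = 5, overlap: float = 0.5, agg: str = "max"
) -> WindowedTable:
    """Sliding-window summarisation.

    The step is ``max(1, floor(w * (1 - overlap)))`` (2 for the default
    w=5, overlap=0.5). Each sensor is summarised by ``agg`` ("max" by
    default, "mean" available). A table shorter than ``w`` yields a single
    truncated window with a warning.
    """
    if w < 1:
        raise CausactError("window size must be >= 1")
    if not 0 <= overlap < 1:
        raise CausactError("overlap must be in [0, 1)")
    if agg not in ("max", "mean"):
        raise CausactError(f"unknown aggregation {agg!r}")
    values = table.data.to_numpy(dtype=float)
    n = len(values)
    step = max(1, int(np.floor(w * (1 - overlap))))
    if n == 0:
        raise CausactError("empty sensor table")
    if n < w:
        warnings.warn(f"table length {n} shorter than window size {w}; truncated window")
        starts = [0]
        spans = [(0, n - 1)]
    else:
        starts = list(range(0, n - w + 1, step))
        spans = [(s, s + w - 1) for s in starts]
    fn = np.nanmax if agg == "max" else np.nanmean
    rows = [fn(values[lo : hi + 1], axis=0) for lo, hi in spans]
    data = pd.DataFrame(rows, columns=table.data.columns)
    data.index.name = "window"
    return WindowedTable(
        data=data,
        spans=spans,
        timestamps=table.data.index.to_numpy(),
        size=w,
        overlap=overlap,
    )


def align_annotation(track: AnnotationTrack, windows: WindowedTable) -> list[str]:
    """One label per window: the annotation label occupying the majority of
    the window's raw span.

    Each raw row in the window is weighted by the time gap to the next raw
    timestamp (the final row gets the mean gap); ties go to the
    earliest-starting label. Spans not covered by the annotation get
    ``(unknown)``.
    """
    ts = windows.timestamps
    if len(ts) > 1:
        gaps = np.diff(ts).astype(float)
        gaps = np.append(gaps, gaps.mean())
    else:
        gaps = np.array([1.0])
    first_seen: dict[str, float] = {}
    for t, lab in track.entries:
        first_seen.setdefault(lab, t)
    out = []
    for lo, hi in windows.spans:
        dur: dict[str, float] = {}
        for i in range(lo, hi + 1):
            lab = track.label_at(ts[i])
            dur[lab] = dur.get(lab, 0.0) + gaps[i]
        best = max(
            dur.items(),
            key=lambda kv: (kv[1], -first_seen.get(kv[0], float("-inf"))),
        )
        out.append(best[0])
    return out
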