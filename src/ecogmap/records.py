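"""Electrode-geometry CSV and saved functional-map records.

Geometry files are plain CSV with the required header ``name,x,y``:
one electrode label plus its normalized 2-D image coordinates per row,
origin at the top-left of the brain image, x rightward and y downward in
[0, 1] (the standard raster-image convention for electrode overlays).

Map records are JSON documents (schema in ``docs/map_record.schema.json``):
subject/task metadata, channel labels, bin times, the display z-score
matrix, the significance mask, trial count, a config snapshot and a
creation timestamp. Unknown top-level keys are preserved on a round trip
for forward compatibility; numbers round-trip at full double precision.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import SchemaError

_GEOMETRY_HEADER = ["name", "x", "y"]
_REQUIRED_RECORD_KEYS = (
    "subject_id",
    "task",
    "channel_labels",
    "bin_times_ms",
    "z_display",
    "significant",
    "n_trials",
)


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Ordered electrode entries: (label, u, v) with u, v in [0, 1]."""

    entries: tuple[tuple[str, float, float], ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    def validate(self) -> None:
        labels = self.labels
        if len(set(labels)) != len(labels):
            raise SchemaError("electrode labels must be unique")
        for name, u, v in self.entries:
            if not (0.0 <= u <= 1.0 and 0.0 <= v <= 1.0):
                raise SchemaError(f"electrode {name!r}: coordinates must lie in [0, 1]")


def read_geometry_csv(path: str | Path) -> ElectrodeGeometry:
    """Parse a geometry CSV, preserving file order; errors name the
    offending 1-based file row."""
    entries: list[tuple[str, float, float]] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected header 'name,x,y'") from None
        if [h.strip().lower() for h in header] != _GEOMETRY_HEADER:
            raise SchemaError(f"{path}: row 1: header must be 'name,x,y'")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != 3:
                raise SchemaError(f"{path}: row {lineno}: expected 3 fields, got {len(row)}")
            name = row[0].strip()
            if not name:
                raise SchemaError(f"{path}: row {lineno}: empty electrode label")
            if name in seen:
                raise SchemaError(f"{path}: row {lineno}: duplicate label {name!r}")
            try:
                u, v = float(row[1]), float(row[2])
            except ValueError:
                raise SchemaError(f"{path}: row {lineno}: malformed coordinate") from None
            if not (0.0 <= u <= 1.0 and 0.0 <= v <= 1.0):
                raise SchemaError(f"{path}: row {lineno}: coordinate outside [0, 1]")
            seen.add(name)
            entries.append((name, u, v))
    return ElectrodeGeometry(tuple(entries))


def write_geometry_csv(geometry: ElectrodeGeometry, path: str | Path) -> None:
    geometry.validate()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_GEOMETRY_HEADER)
        for name, u, v in geometry.entries:
            writer.writerow([name, repr(float(u)), repr(float(v))])


# ---------------------------------------------------------------------------
# map records
# ---------------------------------------------------------------------------

@dataclass
class MapRecord:
    """A saved functional map plus the metadata needed to redisplay it."""

    subject_id: str
    task: str
    channel_labels: tuple[str, ...]
    bin_times_ms: np.ndarray
    z_display: np.ndarray
    significant: np.ndarray
    n_trials: int
    config: dict = field(default_factory=dict)
    created: str = ""
    truncated: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_times_ms = np.asarray(self.bin_times_ms, dtype=np.float64)
        self.z_display = np.asarray(self.z_display, dtype=np.float64)
        self.significant = np.asarray(self.significant, dtype=bool)
        if not self.created:
            self.created = _dt.datetime.now(_dt.timezone.utc).isoformat()
        self.validate()

    def validate(self) -> None:
        shape = (len(self.channel_labels), self.bin_times_ms.size)
        for name in ("z_display", "significant"):
            mat = getattr(self, name)
            if mat.shape != shape:
                raise SchemaError(
                    f"{name} has shape {mat.shape}, expected channels x bins {shape}"
                )
        if self.n_trials < 0:
            raise SchemaError("n_trials must be non-negative")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MapRecord):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.task == other.task
            and self.channel_labels == other.channel_labels
            and np.array_equal(self.bin_times_ms, other.bin_times_ms)
            and np.array_equal(self.z_display, other.z_display, equal_nan=True)
            and np.array_equal(self.significant, other.significant)
            and self.n_trials == other.n_trials
            and self.config == other.config
            and self.created == other.created
            and self.truncated == other.truncated
            and self.extra == other.extra
        )


def _nan_to_null(matrix: np.ndarray) -> list[list[float | None]]:
    return [[None if np.isnan(v) else float(v) for v in row] for row in matrix]


def _null_to_nan(rows: list[list]) -> np.ndarray:
    return np.asarray(
        [[np.nan if v is None else float(v) for v in row] for row in rows], dtype=np.float64
    )


def write_map_record(record: MapRecord, path: str | Path) -> None:
    """Serialize to JSON. Floats use Python's shortest round-trip repr, so
    every value is recovered bit-exactly (well beyond 9 significant digits)."""
    record.validate()
    doc = dict(record.extra)
    doc.update(
        {
            "format": "ecogmap-record",
            "version": 1,
            "subject_id": record.subject_id,
            "task": record.task,
            "channel_labels": list(record.channel_labels),
            "bin_times_ms": [float(t) for t in record.bin_times_ms],
            "z_display": _nan_to_null(record.z_display),
            "significant": [[bool(v) for v in row] for row in record.significant],
            "n_trials": int(record.n_trials),
            "config": record.config,
            "created": record.created,
            "truncated": bool(record.truncated),
        }
    )
    Path(path).write_text(json.dumps(doc, indent=1))


def read_map_record(path: str | Path) -> MapRecord:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from None
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: record must be a JSON object")
    missing = [k for k in _REQUIRED_RECORD_KEYS if k not in doc]
    if missing:
        raise SchemaError(f"{path}: missing required keys {missing}")
    known = set(_REQUIRED_RECORD_KEYS) | {"format", "version", "config", "created", "truncated"}
    extra = {k: v for k, v in doc.items() if k not in known}
    z = _null_to_nan(doc["z_display"]) if doc["z_display"] else np.empty((0, 0))
    sig = (
        np.asarray(doc["significant"], dtype=bool) if doc["significant"] else np.empty((0, 0), bool)
    )
    n_ch, n_bins = len(doc["channel_labels"]), len(doc["bin_times_ms"])
    if z.shape != (n_ch, n_bins) or sig.shape != (n_ch, n_bins):
        raise SchemaError(f"{path}: matrix shapes inconsistent with labels x bin_times")
    return MapRecord(
        subject_id=doc["subject_id"],
        task=doc["task"],
        channel_labels=tuple(doc["channel_labels"]),
        bin_times_ms=np.asarray(doc["bin_times_ms"], dtype=np.float64),
        z_display=z,
        significant=sig,
        n_trials=int(doc["n_trials"]),
        config=doc.get("config", {}),
        created=doc.get("created", ""),
        truncated=bool(doc.get("truncated", False)),
        extra=extra,
    )


def export_map_csv(record: MapRecord, path: str | Path) -> None:
    """Long-format CSV: channel, bin_time_ms, z, significant."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["channel", "bin_time_ms", "z", "significant"])
        for c, label in enumerate(record.channel_labels):
            for b, t_ms in enumerate(record.bin_times_ms):
                z = record.z_display[c, b]
                writer.writerow(
                    [label, float(t_ms), "" if np.isnan(z) else repr(float(z)),
                     int(record.significant[c, b])]
                )
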