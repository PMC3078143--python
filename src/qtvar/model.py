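"""Domain types and interval-series CSV I/O.

The carrier object of the whole pipeline is a :class:`BeatIntervalSeries`:
an ordered per-beat sequence of RR and QT durations (milliseconds) with a
beat annotation (``normal``, ``ectopic`` or ``unreadable``).  Subjects are
:class:`SubjectRecord` objects carrying a series plus cohort labels
(group, recording session) and an exclusion status.

Cohorts travel as a single long-format CSV (RFC 4180, UTF-8, header
required) with columns::

    subject_id, group, session, beat_index, rr_ms, qt_ms, annotation

Intervals are quantised to 0.1 ms on output, which makes the read/write
round-trip lossless for data at 1 kHz-class acquisition precision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANNOTATIONS",
    "GROUPS",
    "SESSIONS",
    "QtvarError",
    "FormatError",
    "ValidationError",
    "TooShortError",
    "StructuralError",
    "DegenerateDataError",
    "BeatIntervalSeries",
    "SubjectRecord",
    "MetricsResult",
    "METRICS_CSV_COLUMNS",
    "read_series",
    "write_series",
    "metrics_to_frame",
]

GROUPS = ("control", "player")
SESSIONS = ("rest", "post_game")
ANNOTATIONS = ("normal", "ectopic", "unreadable")

SERIES_CSV_COLUMNS = [
    "subject_id",
    "group",
    "session",
    "beat_index",
    "rr_ms",
    "qt_ms",
    "annotation",
]


class QtvarError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(QtvarError):
    """A file does not conform to the expected CSV dialect."""


class ValidationError(QtvarError):
    """Data violates a domain invariant (e.g. non-positive interval)."""


class TooShortError(QtvarError):
    """A series is too short for the requested operation/window."""


class StructuralError(QtvarError):
    """A dataset is missing a required group/session cell."""


class DegenerateDataError(QtvarError):
    """Input is degenerate for the requested statistic (e.g. zero spread)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeatIntervalSeries:
    """Ordered per-beat RR/QT durations with annotations.

    Invariants enforced on construction: length >= 1, all intervals
    positive, annotations drawn from :data:`ANNOTATIONS`, and QT < RR on
    every beat annotated ``normal`` (the QT interval is contained in the
    cardiac cycle it belongs to; on ectopic/unreadable beats the measured
    durations are unreliable and the containment is not asserted).
    Beat indices are implicit: position in the arrays, 0-based,
    acquisition order.
    """

    rr_ms: np.ndarray
    qt_ms: np.ndarray
    annotation: np.ndarray

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr_ms, dtype=float)
        qt = np.asarray(self.qt_ms, dtype=float)
        ann = np.asarray(self.annotation, dtype="U10")
        object.__setattr__(self, "rr_ms", rr)
        object.__setattr__(self, "qt_ms", qt)
        object.__setattr__(self, "annotation", ann)
        if rr.ndim != 1 or qt.ndim != 1 or ann.ndim != 1:
            raise ValidationError("series fields must be one-dimensional")
        if not (len(rr) == len(qt) == len(ann)):
            raise ValidationError("rr_ms, qt_ms and annotation lengths differ")
        if len(rr) < 1:
            raise ValidationError("series must contain at least one beat")
        if not np.all(np.isfinite(rr)) or not np.all(np.isfinite(qt)):
            raise ValidationError("intervals must be finite")
        bad = np.flatnonzero(rr <= 0)
        if bad.size:
            raise ValidationError(f"non-positive rr_ms at beat index {bad[0]}")
        bad = np.flatnonzero(qt <= 0)
        if bad.size:
            raise ValidationError(f"non-positive qt_ms at beat index {bad[0]}")
        unknown = ~np.isin(ann, ANNOTATIONS)
        if unknown.any():
            i = int(np.flatnonzero(unknown)[0])
            raise ValidationError(f"unknown annotation {ann[i]!r} at beat index {i}")
        normal = ann == "normal"
        bad = np.flatnonzero(normal & (qt >= rr))
        if bad.size:
            raise ValidationError(
                f"qt_ms >= rr_ms on normal beat at index {bad[0]} "
                f"(qt={qt[bad[0]]:.1f}, rr={rr[bad[0]]:.1f})"
            )

    def __len__(self) -> int:
        return len(self.rr_ms)

    def window(self, start: int, n_beats: int) -> "BeatIntervalSeries":
        """Contiguous sub-series of ``n_beats`` beats starting at ``start``."""
        if start < 0 or start + n_beats > len(self):
            raise TooShortError(
                f"window [{start}, {start + n_beats}) out of range for "
                f"series of {len(self)} beats"
            )
        sl = slice(start, start + n_beats)
        return BeatIntervalSeries(self.rr_ms[sl], self.qt_ms[sl], self.annotation[sl])

    def intervals(self, kind: str) -> np.ndarray:
        """Return the RR or QT duration array (``kind`` in {'rr', 'qt'})."""
        if kind == "rr":
            return self.rr_ms
        if kind == "qt":
            return self.qt_ms
        raise ValueError(f"kind must be 'rr' or 'qt', got {kind!r}")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject-session: interval series plus cohort labels."""

    subject_id: str
    group: str
    session: str
    series: BeatIntervalSeries
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.session not in SESSIONS:
            raise ValidationError(f"unknown session {self.session!r}")
        if self.group == "control" and self.session != "rest":
            raise ValidationError("control subjects only have a rest session")
        if self.excluded != (self.exclusion_reason is not None):
            raise ValidationError(
                "excluded is true if and only if exclusion_reason is set"
            )

    def with_series(self, series: BeatIntervalSeries) -> "SubjectRecord":
        return dataclasses.replace(self, series=series)

    def mark_excluded(self, reason: str) -> "SubjectRecord":
        return dataclasses.replace(self, excluded=True, exclusion_reason=reason)


@dataclass(frozen=True)
class MetricsResult:
    """Per-subject window metrics: means, heart rate, QTc values, STV."""

    subject_id: str
    group: str
    session: str
    mean_rr_ms: float
    mean_qt_ms: float
    heart_rate_bpm: float
    qtc_ms: dict = field(default_factory=dict)  # method name -> ms
    stv_rr_ms: float = 0.0
    stv_qt_ms: float = 0.0
    window_start_index: int = 0

    def __post_init__(self) -> None:
        if self.stv_rr_ms < 0 or self.stv_qt_ms < 0:
            raise ValidationError("short-term variability cannot be negative")


METRICS_CSV_COLUMNS = [
    "subject_id",
    "group",
    "session",
    "mean_rr_ms",
    "hr_bpm",
    "mean_qt_ms",
    "qtc_bazett",
    "qtc_fridericia",
    "qtc_framingham",
    "qtc_hodges",
    "stv_rr",
    "stv_qt",
    "window_start",
]


def metrics_to_frame(results: Iterable[MetricsResult]) -> pd.DataFrame:
    """Tabulate metrics results in the package's per-subject CSV layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "session": r.session,
                "mean_rr_ms": r.mean_rr_ms,
                "hr_bpm": r.heart_rate_bpm,
                "mean_qt_ms": r.mean_qt_ms,
                "qtc_bazett": r.qtc_ms["bazett"],
                "qtc_fridericia": r.qtc_ms["fridericia"],
                "qtc_framingham": r.qtc_ms["framingham"],
                "qtc_hodges": r.qtc_ms["hodges"],
                "stv_rr": r.stv_rr_ms,
                "stv_qt": r.stv_qt_ms,
                "window_start": r.window_start_index,
            }
        )
    return pd.DataFrame(rows, columns=METRICS_CSV_COLUMNS)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def read_series(path: str | Path) -> list[SubjectRecord]:
    """Read a long-format cohort CSV into one record per subject-session.

    Subjects are returned in first-appearance order.  Malformed rows are
    reported with their 1-based file line number (header = line 1).
    Records come back with ``excluded=False``; exclusion is decided by
    the preprocessing stage, not the reader.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such cohort file: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed CSV structure
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in SERIES_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    def _lines(mask: pd.Series) -> list[int]:
        return [int(i) + 2 for i in df.index[mask][:5]]

    for col in ("beat_index", "rr_ms", "qt_ms"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            raise FormatError(
                f"{path}: non-numeric {col} on line(s) {_lines(bad)}"
            )
        df[col] = converted
    for col, ok in (("group", GROUPS), ("session", SESSIONS), ("annotation", ANNOTATIONS)):
        bad = ~df[col].isin(ok)
        if bad.any():
            raise FormatError(
                f"{path}: invalid {col} value on line(s) {_lines(bad)} "
                f"(expected one of {ok})"
            )
    for col in ("rr_ms", "qt_ms"):
        bad = df[col] <= 0
        if bad.any():
            raise ValidationError(
                f"{path}: non-positive {col} on line(s) {_lines(bad)}"
            )

    records: list[SubjectRecord] = []
    # one record per subject-session cell, in first-appearance order
    keys = df[["subject_id", "group", "session"]].drop_duplicates()
    seen: set[str] = set()
    for _, (sid, group, session) in keys.iterrows():
        sub = df[(df["subject_id"] == sid) & (df["session"] == session)]
        if (sub["group"] != group).any():
            raise FormatError(
                f"{path}: subject {sid!r} appears with more than one group label"
            )
        sub = sub.sort_values("beat_index")
        idx = sub["beat_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise FormatError(
                f"{path}: subject {sid!r} session {session!r}: beat_index must "
                f"be contiguous from 0"
            )
        try:
            series = BeatIntervalSeries(
                sub["rr_ms"].to_numpy(float),
                sub["qt_ms"].to_numpy(float),
                sub["annotation"].to_numpy(),
            )
            records.append(SubjectRecord(str(sid), str(group), str(session), series))
        except ValidationError as exc:
            raise ValidationError(f"{path}: subject {sid!r}: {exc}") from exc
        seen.add(f"{sid}/{session}")
    return records


def write_series(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write subject records as a long-format cohort CSV.

    Intervals are quantised to 0.1 ms; an empty record list yields a
    header-only file.  The output is re-readable by :func:`read_series`
    with identical values.
    """
    path = Path(path)
    frames = []
    for rec in records:
        n = len(rec.series)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "session": rec.session,
                    "beat_index": np.arange(n),
                    "rr_ms": rec.series.rr_ms,
                    "qt_ms": rec.series.qt_ms,
                    "annotation": rec.series.annotation,
                }
            )
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)[SERIES_CSV_COLUMNS]
    else:
        out = pd.DataFrame(columns=SERIES_CSV_COLUMNS)
    out.to_csv(path, index=False, float_format="%.1f")
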