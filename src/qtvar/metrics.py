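"""Repolarization metrics: interval averaging, heart rate, QTc, Poincaré
plots and short-term variability (STV).

The short-term variability of an interval series D is

    STV = sum_k |D_{k+1} - D_k| / (30 * sqrt(2))     [ms]

which equals the mean distance of Poincaré points (D_k, D_{k+1}) from the
identity line when the window contributes exactly 30 successive
differences.  Two window conventions are exposed:

``matched``
    31-beat window, 30 differences — the normalising constant is the true
    difference count and the sum formula coincides exactly with the mean
    orthogonal Poincaré distance.  This is the default.
``literal``
    30-beat window, 29 differences, same 30*sqrt(2) normaliser — provided
    for sensitivity analysis against the stricter reading of a "30
    consecutive beats" window.

Four heart-rate corrections of QT are implemented (all arguments in ms):

    Bazett       QTc = QT / sqrt(RR/1000)
    Fridericia   QTc = QT / (RR/1000)^(1/3)
    Framingham   QTc = QT + 0.154 * (1000 - RR)
    Hodges       QTc = QT + 1.75 * (60000/RR - 60)

Bazett's formula is dimensionally inconsistent as printed in most sources;
RR is taken in seconds (RR/1000), consistent with the explicit /1000 in
the Fridericia form, and the output stays in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import (
    BeatIntervalSeries,
    MetricsResult,
    SubjectRecord,
    TooShortError,
    ValidationError,
)
from .preprocess import WINDOW_BEATS, select_window

__all__ = [
    "QTC_METHODS",
    "STV_NORMALISER",
    "AnalysisConfig",
    "PoincarePlot",
    "mean_interval",
    "heart_rate",
    "qtc",
    "poincare",
    "stv",
    "stv_poincare_oracle",
    "compute_metrics",
]

#: normalising constant of the STV formula, 30*sqrt(2)
STV_NORMALISER = 30.0 * math.sqrt(2.0)

QTC_METHODS = ("bazett", "fridericia", "framingham", "hodges")

#: number of successive differences contributed by each window mode
_N_DIFFS = {"matched": 30, "literal": 29}


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the per-subject analysis stage.

    mode: STV window convention ("matched" = 31 beats / "literal" = 30).
    ectopic_tolerance: RR prematurity fraction for ectopy flagging.
    ectopic_threshold / noise_threshold: subject exclusion fractions.
    """

    mode: str = "matched"
    ectopic_tolerance: float = 0.20
    ectopic_threshold: float = 0.05
    noise_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in WINDOW_BEATS:
            raise ValueError(f"mode must be 'matched' or 'literal', got {self.mode!r}")

    @property
    def window_beats(self) -> int:
        return WINDOW_BEATS[self.mode]


@dataclass(frozen=True)
class PoincarePlot:
    """Ordered (D_k, D_{k+1}) pairs for one interval kind."""

    points: np.ndarray  # shape (B-1, 2)
    interval_kind: str  # "rr" | "qt"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError("Poincaré points must have shape (n, 2)")
        if self.interval_kind not in ("rr", "qt"):
            raise ValueError(f"interval_kind must be 'rr' or 'qt', got {self.interval_kind!r}")

    def __len__(self) -> int:
        return len(self.points)


def mean_interval(window: BeatIntervalSeries, kind: str) -> float:
    """Arithmetic mean of RR or QT over the window, in ms."""
    if len(window) < 1:
        raise TooShortError("cannot average an empty window")
    return float(np.mean(window.intervals(kind)))


def heart_rate(mean_rr: float) -> float:
    """Heart rate in beats/min from a mean RR interval in ms."""
    if mean_rr <= 0:
        raise ValidationError(f"mean RR must be positive, got {mean_rr}")
    return 60000.0 / mean_rr


def qtc(qt: float, rr: float, method: str) -> float:
    """Heart-rate–corrected QT interval, ms in / ms out."""
    if np.any(np.asarray(qt) <= 0) or np.any(np.asarray(rr) <= 0):
        raise ValidationError("qt and rr must be positive")
    if method == "bazett":
        return qt / np.sqrt(rr / 1000.0)
    if method == "fridericia":
        return qt / np.cbrt(rr / 1000.0)
    if method == "framingham":
        return qt + 0.154 * (1000.0 - rr)
    if method == "hodges":
        return qt + 1.75 * (60000.0 / rr - 60.0)
    raise ValueError(f"unknown QTc method {method!r}; choose from {QTC_METHODS}")


def poincare(window: BeatIntervalSeries, kind: str) -> PoincarePlot:
    """Poincaré plot: each interval against its predecessor (B-1 points)."""
    if len(window) < 2:
        raise TooShortError("Poincaré plot needs at least 2 beats")
    d = window.intervals(kind)
    return PoincarePlot(np.column_stack([d[:-1], d[1:]]), kind)


def _stv_from_values(values: np.ndarray) -> float:
    return float(np.sum(np.abs(np.diff(values))) / STV_NORMALISER)


def stv(window: BeatIntervalSeries, kind: str, mode: str = "matched") -> float:
    """Short-term variability of the RR or QT interval over one window.

    The window length is strict: 31 beats in ``matched`` mode, 30 in
    ``literal`` mode; the normaliser is 30*sqrt(2) in both.
    """
    if mode not in _N_DIFFS:
        raise ValueError(f"mode must be 'matched' or 'literal', got {mode!r}")
    expected = _N_DIFFS[mode] + 1
    if len(window) != expected:
        raise TooShortError(
            f"{mode} mode requires a {expected}-beat window, got {len(window)}"
        )
    return _stv_from_values(window.intervals(kind))


def stv_poincare_oracle(plot: PoincarePlot) -> float:
    """STV as mean orthogonal distance of Poincaré points from identity.

    The distance of (d_k, d_{k+1}) from the line y = x is
    |d_{k+1} - d_k| / sqrt(2); with exactly 30 points this mean equals
    the sum-formula STV of the matched 31-beat window.
    """
    if len(plot) != 30:
        raise ValidationError(
            f"orthogonal-distance oracle requires exactly 30 points, got {len(plot)}"
        )
    d = plot.points
    return float(np.mean(np.abs(d[:, 1] - d[:, 0])) / math.sqrt(2.0))


def compute_metrics(
    record: SubjectRecord, config: AnalysisConfig | None = None
) -> MetricsResult:
    """All per-subject metrics from one shared clean window.

    The window (31 beats matched / 30 literal) feeds the interval means,
    heart rate, all four QTc values (computed from the window-mean QT and
    RR, not beat-by-beat) and both STV values.  The record must not be
    excluded and must contain a clean window.
    """
    if config is None:
        config = AnalysisConfig()
    if record.excluded:
        raise ValidationError(
            f"subject {record.subject_id!r} is excluded ({record.exclusion_reason})"
        )
    start, window = select_window(record.series, config.window_beats)
    mean_rr = mean_interval(window, "rr")
    mean_qt = mean_interval(window, "qt")
    return MetricsResult(
        subject_id=record.subject_id,
        group=record.group,
        session=record.session,
        mean_rr_ms=mean_rr,
        mean_qt_ms=mean_qt,
        heart_rate_bpm=heart_rate(mean_rr),
        qtc_ms={m: float(qtc(mean_qt, mean_rr, m)) for m in QTC_METHODS},
        stv_rr_ms=stv(window, "rr", config.mode),
        stv_qt_ms=stv(window, "qt", config.mode),
        window_start_index=start,
    )
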