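"""Subject exclusion rules and clean-window selection.

A subject is dropped from analysis when more than 5% of beats are ectopic
(strict inequality), when more than 5% are unreadable (noise), or when no
contiguous run of clean beats long enough for the analysis window exists.

Ectopic beats are detected from RR prematurity/delay: a beat whose RR
deviates from the running median of the previous five non-ectopic RR
values by more than a tolerance (default 20%) is re-annotated ectopic.
Pre-existing annotations are never un-flagged, which makes the detector
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import BeatIntervalSeries, SubjectRecord, TooShortError

__all__ = [
    "ExclusionReport",
    "flag_ectopic_beats",
    "apply_exclusion",
    "select_window",
    "preprocess_record",
    "EXCLUSION_CSV_COLUMNS",
]

EXCLUSION_CSV_COLUMNS = [
    "subject_id",
    "n_beats",
    "n_ectopic",
    "n_unreadable",
    "ectopic_fraction",
    "excluded",
    "reason",
]

#: window sizes: "matched" uses 31 beats (30 successive differences, so the
#: 30*sqrt(2) normaliser is the true difference count); "literal" uses 30
#: beats (29 differences) with the same normaliser.
WINDOW_BEATS = {"matched": 31, "literal": 30}


@dataclass(frozen=True)
class ExclusionReport:
    subject_id: str
    n_beats: int
    n_ectopic: int
    n_unreadable: int
    ectopic_fraction: float
    excluded: bool
    reason: str | None = None  # ectopic_excess | noise_excess | too_short

    def __post_init__(self) -> None:
        if self.excluded and self.reason is None:
            raise ValueError("excluded report must carry a reason")
        if not self.excluded and self.reason is not None:
            raise ValueError("retained report must not carry a reason")


def flag_ectopic_beats(
    series: BeatIntervalSeries, tolerance: float = 0.20
) -> BeatIntervalSeries:
    """Annotate RR-premature/delayed beats as ectopic.

    A beat annotated ``normal`` becomes ``ectopic`` when its RR deviates
    from the running median of the previous five non-ectopic RR values by
    more than ``tolerance`` (as a fraction of that median).  Flagged
    beats are withheld from the running buffer, so a single premature
    beat does not poison the reference for its successors.  Beats before
    five non-ectopic predecessors exist are never flagged.
    """
    if not 0 < tolerance < 1:
        raise ValueError(f"tolerance must be in (0, 1), got {tolerance}")
    if len(series) < 6:
        raise TooShortError(
            f"ectopy detection needs at least 6 beats, got {len(series)}"
        )
    rr = series.rr_ms
    ann = series.annotation.copy()
    # fast path: with no ectopic annotations yet, the running buffer is just
    # the previous beats, so the sliding median is vectorisable; the loop is
    # only needed once a beat actually gets flagged (or was pre-flagged).
    if not np.any(ann == "ectopic"):
        med = np.median(
            np.lib.stride_tricks.sliding_window_view(rr[:-1], 5), axis=1
        )  # med[i] serves beat i + 5
        dev = np.abs(rr[5:] - med) > tolerance * med
        if not np.any(dev & (ann[5:] == "normal")):
            return series
    recent: list[float] = []  # RR of non-ectopic beats seen so far
    for i in range(len(series)):
        if ann[i] != "ectopic" and len(recent) >= 5:
            med = float(np.median(recent[-5:]))
            if ann[i] == "normal" and abs(rr[i] - med) > tolerance * med:
                ann[i] = "ectopic"
        if ann[i] != "ectopic":
            recent.append(float(rr[i]))
    return BeatIntervalSeries(rr, series.qt_ms, ann)


def select_window(
    series: BeatIntervalSeries, n_beats: int
) -> tuple[int, BeatIntervalSeries]:
    """First contiguous run of ``n_beats`` beats all annotated normal.

    Deterministic for fixed input (the earliest clean run wins).  Raises
    :class:`TooShortError` when no such run exists.
    """
    if n_beats < 2:
        raise ValueError(f"n_beats must be >= 2, got {n_beats}")
    normal = series.annotation == "normal"
    run = 0
    for i, ok in enumerate(normal):
        run = run + 1 if ok else 0
        if run == n_beats:
            start = i - n_beats + 1
            return start, series.window(start, n_beats)
    raise TooShortError(
        f"no run of {n_beats} consecutive normal beats in {len(series)}-beat series"
    )


def apply_exclusion(
    record: SubjectRecord,
    ectopic_threshold: float = 0.05,
    noise_threshold: float = 0.05,
    window_beats: int = WINDOW_BEATS["matched"],
) -> ExclusionReport:
    """Decide whether a subject enters the analysis.

    Excluded with reason ``ectopic_excess`` iff the ectopic fraction
    strictly exceeds ``ectopic_threshold`` (the rule is ">5%", so exactly
    5% is retained); ``noise_excess`` iff the unreadable fraction strictly
    exceeds ``noise_threshold``; ``too_short`` iff no clean window of
    ``window_beats`` consecutive normal beats exists.  Annotations are
    taken as given — run :func:`flag_ectopic_beats` first.
    """
    for name, thr in (("ectopic", ectopic_threshold), ("noise", noise_threshold)):
        if not 0 < thr <= 1:
            raise ValueError(f"{name}_threshold must be in (0, 1], got {thr}")
    ann = record.series.annotation
    n = len(record.series)
    n_ect = int(np.count_nonzero(ann == "ectopic"))
    n_unr = int(np.count_nonzero(ann == "unreadable"))
    frac_e = n_ect / n
    frac_u = n_unr / n
    reason: str | None = None
    if frac_e > ectopic_threshold:
        reason = "ectopic_excess"
    elif frac_u > noise_threshold:
        reason = "noise_excess"
    else:
        try:
            select_window(record.series, window_beats)
        except TooShortError:
            reason = "too_short"
    return ExclusionReport(
        subject_id=record.subject_id,
        n_beats=n,
        n_ectopic=n_ect,
        n_unreadable=n_unr,
        ectopic_fraction=frac_e,
        excluded=reason is not None,
        reason=reason,
    )


def preprocess_record(
    record: SubjectRecord,
    ectopic_tolerance: float = 0.20,
    ectopic_threshold: float = 0.05,
    noise_threshold: float = 0.05,
    window_beats: int = WINDOW_BEATS["matched"],
) -> tuple[SubjectRecord, ExclusionReport]:
    """Flag ectopy, apply the exclusion rules, and return the updated record."""
    flagged = record.with_series(flag_ectopic_beats(record.series, ectopic_tolerance))
    report = apply_exclusion(flagged, ectopic_threshold, noise_threshold, window_beats)
    if report.excluded:
        flagged = flagged.mark_excluded(report.reason)
    return flagged, report
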