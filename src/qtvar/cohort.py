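"""Cohort statistics: group summaries, fixed-bin histograms and the
group comparisons of the study design (unpaired t between independent
groups, one-way ANOVA plus paired t across repeated sessions).

Group values are summarised as mean ± SEM (SD/sqrt(n), sample SD with
n-1 denominator).  "Student's t-test" is the equal-variance pooled test;
Welch's correction is available behind a flag.  Significance stars follow
the usual figure-legend convention: * p<0.05, ** p<0.01, *** p<0.001.
No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    DegenerateDataError,
    MetricsResult,
    StructuralError,
    ValidationError,
    metrics_to_frame,
)

__all__ = [
    "METRIC_COLUMNS",
    "GroupSummary",
    "Histogram",
    "CohortSummary",
    "summarize_group",
    "histogram",
    "unpaired_t",
    "paired_t",
    "one_way_anova",
    "significance_stars",
    "compare_cohorts",
    "write_cohort_summary",
]

#: per-subject metric columns entering every summary and comparison
METRIC_COLUMNS = [
    "mean_rr_ms",
    "hr_bpm",
    "mean_qt_ms",
    "qtc_bazett",
    "qtc_fridericia",
    "qtc_framingham",
    "qtc_hodges",
    "stv_rr",
    "stv_qt",
]

#: histogram bin widths per metric, following the study's figure bins
HISTOGRAM_BINS = {"mean_qt_ms": 10.0, "stv_qt": 0.5}

#: the three cohort cells of the study design
CELLS = [("control", "rest"), ("player", "rest"), ("player", "post_game")]


@dataclass(frozen=True)
class GroupSummary:
    group: str
    session: str
    n: int
    stats: dict = field(default_factory=dict)  # metric -> (mean, sd, sem)


@dataclass(frozen=True)
class Histogram:
    metric: str
    group: str
    session: str
    bin_size: float
    bin_edges: np.ndarray  # len(counts) + 1, multiples of bin_size
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if len(edges) != len(counts) + 1:
            raise ValidationError("histogram needs len(edges) == len(counts) + 1")


@dataclass(frozen=True)
class CohortSummary:
    summaries: list  # of GroupSummary
    comparisons: pd.DataFrame
    anova: pd.DataFrame
    histograms: list  # of Histogram


def _as_frame(metrics: Iterable[MetricsResult] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(metrics, pd.DataFrame):
        return metrics
    return metrics_to_frame(list(metrics))


def summarize_group(metrics: Iterable[MetricsResult] | pd.DataFrame) -> GroupSummary:
    """Mean, sample SD and SEM of every metric for one group/session cell."""
    df = _as_frame(metrics)
    n = len(df)
    if n < 2:
        raise ValidationError(f"group summary needs n >= 2 subjects, got {n}")
    group = df["group"].iloc[0]
    session = df["session"].iloc[0]
    if (df["group"] != group).any() or (df["session"] != session).any():
        raise ValidationError("summarize_group expects a single group/session cell")
    out = {}
    for m in METRIC_COLUMNS:
        vals = df[m].to_numpy(float)
        sd = float(np.std(vals, ddof=1))
        out[m] = (float(np.mean(vals)), sd, sd / np.sqrt(n))
    return GroupSummary(group=group, session=session, n=n, stats=out)


def histogram(
    values: Sequence[float],
    bin_size: float,
    metric: str = "",
    group: str = "",
    session: str = "",
) -> Histogram:
    """Counts over contiguous half-open bins [k*b, (k+1)*b) anchored at 0."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValidationError("histogram needs at least one value")
    if bin_size <= 0:
        raise ValidationError(f"bin_size must be positive, got {bin_size}")
    k = np.floor(vals / bin_size).astype(int)
    k0, k1 = int(k.min()), int(k.max())
    counts = np.bincount(k - k0, minlength=k1 - k0 + 1)
    edges = np.arange(k0, k1 + 2) * bin_size
    return Histogram(metric, group, session, bin_size, edges, counts)


def _check_group(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValidationError(f"{name} needs n >= 2, got {arr.size}")
    return arr


def unpaired_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test; pooled variance by default.

    Returns (t, df, p).  With ``welch=True`` the unequal-variance form
    with Welch–Satterthwaite df is used instead.
    """
    a = _check_group(a, "group a")
    b = _check_group(b, "group b")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = res.df if welch else len(a) + len(b) - 2
    return float(res.statistic), float(df), float(res.pvalue)


def paired_t(pre: Sequence[float], post: Sequence[float]) -> tuple[float, float, float]:
    """Two-sided paired t-test on within-subject differences (post - pre)."""
    pre = _check_group(pre, "pre")
    post = _check_group(post, "post")
    if len(pre) != len(post):
        raise ValidationError(
            f"paired test needs equal lengths, got {len(pre)} and {len(post)}"
        )
    diff = post - pre
    if np.std(diff, ddof=1) == 0:
        if np.mean(diff) == 0:
            return 0.0, float(len(diff) - 1), 1.0
        raise DegenerateDataError(
            "all within-subject differences are identical and nonzero: "
            "the t statistic is infinite"
        )
    res = stats.ttest_rel(post, pre)
    return float(res.statistic), float(len(diff) - 1), float(res.pvalue)


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA; returns (F, df_between, df_within, p).

    For exactly two groups F equals the square of the pooled unpaired t.
    """
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least 2 groups")
    arrays = [_check_group(g, f"group {i}") for i, g in enumerate(groups)]
    res = stats.f_oneway(*arrays)
    df1 = len(arrays) - 1
    df2 = sum(len(a) for a in arrays) - len(arrays)
    f = float(res.statistic)
    if np.isnan(f):  # all values identical in every group
        f = 0.0
        p = 1.0
    else:
        p = float(res.pvalue)
    return f, df1, df2, p


def significance_stars(p: float) -> str:
    """Figure-legend star notation for a p value."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _cell(df: pd.DataFrame, group: str, session: str) -> pd.DataFrame:
    return df[(df["group"] == group) & (df["session"] == session)]


def compare_cohorts(
    metrics: Iterable[MetricsResult] | pd.DataFrame,
    welch: bool = False,
    require_complete: bool = True,
) -> CohortSummary:
    """Every group comparison of the study design, for every metric.

    Unpaired tests: control vs players at rest, control vs players
    post-game.  Within players: one-way ANOVA across sessions followed by
    a paired rest-vs-post-game t-test (paired on subject_id; subjects
    present in only one session drop out of the pair).  A three-cell
    ANOVA over all cells is reported as well.

    With ``require_complete=True`` a missing group/session cell raises
    :class:`StructuralError`; otherwise only the feasible comparisons are
    emitted.
    """
    df = _as_frame(metrics)
    cells = {gs: _cell(df, *gs) for gs in CELLS}
    missing = [gs for gs, sub in cells.items() if len(sub) < 2]
    if missing and require_complete:
        raise StructuralError(
            f"dataset is missing group/session cell(s): "
            f"{['/'.join(gs) for gs in missing]}"
        )
    present = {gs: sub for gs, sub in cells.items() if len(sub) >= 2}

    summaries = [summarize_group(sub) for sub in present.values()]
    by_cell = {(s.group, s.session): s for s in summaries}

    comp_rows = []
    anova_rows = []

    def _unpaired(metric, cell_a, cell_b, label):
        a = present[cell_a][metric].to_numpy(float)
        b = present[cell_b][metric].to_numpy(float)
        t, dof, p = unpaired_t(a, b, welch=welch)
        comp_rows.append(
            {
                "metric": metric,
                "comparison": label,
                "test": "unpaired_t" if not welch else "welch_t",
                "estimate_a": by_cell[cell_a].stats[metric][0],
                "estimate_b": by_cell[cell_b].stats[metric][0],
                "sem_a": by_cell[cell_a].stats[metric][2],
                "sem_b": by_cell[cell_b].stats[metric][2],
                "statistic": t,
                "df": dof,
                "p": p,
                "stars": significance_stars(p),
            }
        )

    rest = ("player", "rest")
    post = ("player", "post_game")
    ctrl = ("control", "rest")
    paired_ids = None
    if rest in present and post in present:
        paired_ids = sorted(
            set(present[rest]["subject_id"]) & set(present[post]["subject_id"])
        )

    for metric in METRIC_COLUMNS:
        if ctrl in present and rest in present:
            _unpaired(metric, ctrl, rest, "control_vs_player_rest")
        if ctrl in present and post in present:
            _unpaired(metric, ctrl, post, "control_vs_player_post_game")
        if paired_ids and len(paired_ids) >= 2:
            a = (
                present[rest].set_index("subject_id")[metric].loc[paired_ids]
                .to_numpy(float)
            )
            b = (
                present[post].set_index("subject_id")[metric].loc[paired_ids]
                .to_numpy(float)
            )
            f, df1, df2, p_a = one_way_anova([a, b])
            anova_rows.append(
                {
                    "metric": metric,
                    "comparison": "player_sessions",
                    "F": f,
                    "df1": df1,
                    "df2": df2,
                    "p": p_a,
                    "stars": significance_stars(p_a),
                }
            )
            t, dof, p = paired_t(a, b)
            comp_rows.append(
                {
                    "metric": metric,
                    "comparison": "player_rest_vs_post_game",
                    "test": "paired_t",
                    "estimate_a": by_cell[rest].stats[metric][0],
                    "estimate_b": by_cell[post].stats[metric][0],
                    "sem_a": by_cell[rest].stats[metric][2],
                    "sem_b": by_cell[post].stats[metric][2],
                    "statistic": t,
                    "df": dof,
                    "p": p,
                    "stars": significance_stars(p),
                }
            )
        if len(present) == 3:
            f, df1, df2, p_a = one_way_anova(
                [present[gs][metric].to_numpy(float) for gs in CELLS]
            )
            anova_rows.append(
                {
                    "metric": metric,
                    "comparison": "all_cells",
                    "F": f,
                    "df1": df1,
                    "df2": df2,
                    "p": p_a,
                    "stars": significance_stars(p_a),
                }
            )

    histograms = []
    for metric, bin_size in HISTOGRAM_BINS.items():
        for (group, session), sub in present.items():
            histograms.append(
                histogram(
                    sub[metric].to_numpy(float), bin_size, metric, group, session
                )
            )

    return CohortSummary(
        summaries=summaries,
        comparisons=pd.DataFrame(
            comp_rows,
            columns=[
                "metric",
                "comparison",
                "test",
                "estimate_a",
                "estimate_b",
                "sem_a",
                "sem_b",
                "statistic",
                "df",
                "p",
                "stars",
            ],
        ),
        anova=pd.DataFrame(
            anova_rows,
            columns=["metric", "comparison", "F", "df1", "df2", "p", "stars"],
        ),
        histograms=histograms,
    )


def write_cohort_summary(summary: CohortSummary, out_dir: str | Path) -> list[Path]:
    """Serialise a cohort summary to CSV files; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []

    rows = []
    for s in summary.summaries:
        for metric, (mean, sd, sem) in s.stats.items():
            rows.append(
                {
                    "group": s.group,
                    "session": s.session,
                    "n": s.n,
                    "metric": metric,
                    "mean": mean,
                    "sd": sd,
                    "sem": sem,
                }
            )
    p = out_dir / "group_summaries.csv"
    pd.DataFrame(rows).to_csv(p, index=False, float_format="%.6g")
    paths.append(p)

    p = out_dir / "comparisons.csv"
    summary.comparisons.to_csv(p, index=False, float_format="%.6g")
    paths.append(p)

    p = out_dir / "anova.csv"
    summary.anova.to_csv(p, index=False, float_format="%.6g")
    paths.append(p)

    rows = []
    for h in summary.histograms:
        for edge, count in zip(h.bin_edges[:-1], h.counts):
            rows.append(
                {
                    "metric": h.metric,
                    "group": h.group,
                    "session": h.session,
                    "bin_size": h.bin_size,
                    "edge": edge,
                    "count": count,
                }
            )
    p = out_dir / "histograms.csv"
    pd.DataFrame(rows).to_csv(p, index=False, float_format="%.6g")
    paths.append(p)
    return paths
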