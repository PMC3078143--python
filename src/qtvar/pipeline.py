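"""End-to-end orchestration: preprocess a cohort and compute per-subject
metrics.  The CLI and the reproduction script both run through here."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .cohort import CohortSummary, compare_cohorts
from .metrics import AnalysisConfig, compute_metrics
from .model import MetricsResult, SubjectRecord, metrics_to_frame
from .preprocess import ExclusionReport, preprocess_record
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["analyze_cohort", "run_study"]


def analyze_cohort(
    records: Sequence[SubjectRecord], config: AnalysisConfig | None = None
) -> tuple[list[MetricsResult], list[ExclusionReport]]:
    """Flag ectopy, apply exclusions and compute metrics for every subject.

    Returns metrics for retained subjects only, plus one exclusion report
    per input record.
    """
    if config is None:
        config = AnalysisConfig()
    results: list[MetricsResult] = []
    reports: list[ExclusionReport] = []
    for rec in records:
        processed, report = preprocess_record(
            rec,
            ectopic_tolerance=config.ectopic_tolerance,
            ectopic_threshold=config.ectopic_threshold,
            noise_threshold=config.noise_threshold,
            window_beats=config.window_beats,
        )
        reports.append(report)
        if not processed.excluded:
            results.append(compute_metrics(processed, config))
    return results, reports


def run_study(
    generator_config: GeneratorConfig, analysis_config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, CohortSummary]:
    """Simulate a cohort, analyze it, and compare the groups.

    Returns the per-subject metrics table and the cohort summary.
    """
    records, _ = generate_cohort(generator_config)
    results, _ = analyze_cohort(records, analysis_config)
    frame = metrics_to_frame(results)
    summary = compare_cohorts(frame)
    return frame, summary
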