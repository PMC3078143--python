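"""Group summaries, histograms and statistical comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

from qtvar import (
    DegenerateDataError,
    StructuralError,
    ValidationError,
    compare_cohorts,
    histogram,
    one_way_anova,
    paired_t,
    significance_stars,
    summarize_group,
    unpaired_t,
)
from qtvar.cohort import METRIC_COLUMNS


def metrics_frame(cells):
    """Tiny metrics table; cells = {(group, session): {metric: values}}."""
    rows = []
    for (group, session), overrides in cells.items():
        n = len(next(iter(overrides.values())))
        # non-constant fillers keep the t/F statistics well defined
        offset = sum(map(ord, group + session)) % 7
        base = {
            m: 100.0 + offset + np.linspace(0.0, 1.0 + 0.1 * offset, n)
            for m in METRIC_COLUMNS
        }
        base.update({k: np.asarray(v, float) for k, v in overrides.items()})
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{group}_{i:03d}",
                    "group": group,
                    "session": session,
                    "window_start": 0,
                    **{m: base[m][i] for m in METRIC_COLUMNS},
                }
            )
    return pd.DataFrame(rows)


class TestSummaries:
    def test_hand_computed_mean_sd_sem(self):
        df = metrics_frame({("control", "rest"): {"stv_qt": [1.0, 2.0, 3.0]}})
        s = summarize_group(df)
        mean, sd, sem = s.stats["stv_qt"]
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)
        assert sem == pytest.approx(0.5774, abs=1e-4)

    def test_identical_values_zero_spread(self):
        df = metrics_frame({("control", "rest"): {"stv_qt": [2.0] * 5}})
        _, sd, sem = summarize_group(df).stats["stv_qt"]
        assert sd == 0.0 and sem == 0.0

    def test_single_subject_rejected(self):
        df = metrics_frame({("control", "rest"): {"stv_qt": [2.0]}})
        with pytest.raises(ValidationError):
            summarize_group(df)


class TestHistogram:
    def test_half_open_bins_anchored_at_zero(self):
        h = histogram([3.1, 3.4, 3.6], bin_size=0.5)
        assert h.bin_edges[0] == pytest.approx(3.0)
        assert h.counts.tolist() == [2, 1]

    def test_single_value(self):
        h = histogram([417.0], bin_size=10.0)
        assert h.counts.tolist() == [1]
        assert h.bin_edges[0] == pytest.approx(410.0)

    def test_counts_conserved(self, rng):
        vals = rng.normal(400, 25, size=137)
        h = histogram(vals, bin_size=10.0)
        assert h.counts.sum() == 137

    def test_value_on_edge_goes_right(self):
        h = histogram([3.5], bin_size=0.5)
        assert h.bin_edges[0] == pytest.approx(3.5)


class TestTests:
    def test_unpaired_hand_value(self):
        t, df, p = unpaired_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == 4
        assert 0 < p <= 1

    def test_unpaired_identical_groups(self):
        t, _, p = unpaired_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_welch_flag_changes_df(self):
        _, df_pooled, _ = unpaired_t([1, 2, 3], [2, 4, 6, 8])
        _, df_welch, _ = unpaired_t([1, 2, 3], [2, 4, 6, 8], welch=True)
        assert df_pooled == 5 and df_welch != 5

    def test_paired_hand_value(self):
        t, df, _ = paired_t([1, 2, 3], [2, 2, 5])
        assert t == pytest.approx(math.sqrt(3.0), abs=1e-4)
        assert df == 2

    def test_paired_identical_is_zero(self):
        t, _, p = paired_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_paired_constant_shift_degenerate(self):
        with pytest.raises(DegenerateDataError):
            paired_t([1, 2, 3], [2, 3, 4])

    def test_anova_two_groups_equals_t_squared(self):
        f, df1, df2, _ = one_way_anova([[1, 2, 3], [2, 3, 4]])
        assert f == pytest.approx(1.5)
        assert (df1, df2) == (1, 4)

    def test_anova_identical_groups_zero(self):
        f, *_ = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert f == 0.0

    def test_anova_three_groups_vs_sums_of_squares_oracle(self):
        groups = [[1.0, 2.0, 4.0], [3.0, 5.0, 4.0], [7.0, 6.0, 8.0]]
        # brute-force between/within sums of squares
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
        ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
        expected = (ssb / 2) / (ssw / 6)
        f, df1, df2, _ = one_way_anova(groups)
        assert f == pytest.approx(expected, rel=1e-12)
        assert (df1, df2) == (2, 6)

    @pytest.mark.parametrize(
        "p, expected",
        [(0.2, ""), (0.049, "*"), (0.009, "**"), (0.0009, "***")],
    )
    def test_stars(self, p, expected):
        assert significance_stars(p) == expected


class TestCompareCohorts:
    def three_cell_frame(self, rng, shift=1.3):
        n = 20
        return metrics_frame(
            {
                ("control", "rest"): {"stv_qt": rng.normal(3.5, 0.9, n)},
                ("player", "rest"): {"stv_qt": rng.normal(3.5 + shift, 1.2, n)},
                ("player", "post_game"): {"stv_qt": rng.normal(4.3, 1.2, n)},
            }
        )

    def test_elevated_group_detected(self, rng):
        summary = compare_cohorts(self.three_cell_frame(rng))
        row = summary.comparisons.query(
            "metric == 'stv_qt' and comparison == 'control_vs_player_rest'"
        ).iloc[0]
        assert row["estimate_b"] > row["estimate_a"]
        assert row["p"] < 0.05

    def test_every_metric_and_comparison_emitted(self, rng):
        summary = compare_cohorts(self.three_cell_frame(rng))
        assert set(summary.comparisons["metric"]) == set(METRIC_COLUMNS)
        assert set(summary.comparisons["comparison"]) == {
            "control_vs_player_rest",
            "control_vs_player_post_game",
            "player_rest_vs_post_game",
        }
        # ANOVA runs both within players and across all three cells
        assert set(summary.anova["comparison"]) == {"player_sessions", "all_cells"}

    def test_paired_rows_use_subject_pairing(self, rng):
        df = self.three_cell_frame(rng)
        row = compare_cohorts(df).comparisons.query(
            "comparison == 'player_rest_vs_post_game' and metric == 'stv_qt'"
        ).iloc[0]
        assert row["test"] == "paired_t"
        assert row["df"] == 19  # n - 1 pairs

    def test_missing_cell_is_structural_error(self, rng):
        df = self.three_cell_frame(rng)
        df = df[~((df["group"] == "player") & (df["session"] == "post_game"))]
        with pytest.raises(StructuralError, match="post_game"):
            compare_cohorts(df)

    def test_lenient_mode_skips_missing_comparisons(self, rng):
        df = self.three_cell_frame(rng)
        df = df[df["group"] == "control"]
        summary = compare_cohorts(df, require_complete=False)
        assert summary.comparisons.empty
        assert len(summary.summaries) == 1

    def test_histograms_follow_figure_bins(self, rng):
        summary = compare_cohorts(self.three_cell_frame(rng))
        bins = {h.metric: h.bin_size for h in summary.histograms}
        assert bins == {"mean_qt_ms": 10.0, "stv_qt": 0.5}
        assert all(h.counts.sum() == 20 for h in summary.histograms)
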