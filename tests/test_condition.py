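"""Frequency weighting, severity scaling, and condition aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benthochange import (
    METRICS,
    build_weight_tables,
    factor_condition_summary,
    frequency_weights,
    individual_condition,
    score_table,
    severity_scaled_score,
    tabulate_metric_counts,
)
from conftest import make_annotations


class TestTabulate:
    def test_hand_tally(self, t1_cohort):
        counts, n_total = tabulate_metric_counts(t1_cohort, "growth")
        assert counts == {1: 2, 2: 1, 3: 1}
        assert n_total == 4

    def test_all_zero_scores_error(self):
        df = make_annotations([{}, {}])
        with pytest.raises(ValueError, match="no condition changes"):
            tabulate_metric_counts(df, "growth")

    def test_unobserved_top_level_absent_from_counts(self, t1_cohort):
        counts, _ = tabulate_metric_counts(t1_cohort, "growth")
        assert 4 not in counts

    def test_global_denominator_counts_any_change(self, t1_cohort):
        # four individuals changed on some metric; only one has tissue loss,
        # but the global denominator counts any-change individuals
        _, n_total = tabulate_metric_counts(t1_cohort, "tissue_loss",
                                            denominator="global")
        assert n_total == 4


class TestFrequencyWeights:
    def test_cumulative_proportions(self):
        wt = frequency_weights({1: 2, 2: 1, 3: 1}, 4, "growth")
        assert wt.weights == {0: 0.0, 1: 0.5, 2: 0.75, 3: 1.0, 4: 1.0}

    def test_single_level_reaches_one(self):
        wt = frequency_weights({4: 7}, 7, "tissue_loss")
        assert wt.weights[4] == 1.0

    def test_empty_level_carried_forward(self):
        wt = frequency_weights({1: 1, 3: 1}, 2, "growth")
        assert wt.weights[2] == wt.weights[1] == 0.5

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            frequency_weights({1: 1}, 0, "growth")

    def test_out_of_range_keys_rejected(self):
        with pytest.raises(ValueError):
            frequency_weights({3: 1}, 1, "orientation")

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(1, 4), min_size=1, max_size=40))
    def test_weights_nondecreasing_and_max_observed_is_one(self, scores):
        counts = {s: scores.count(s) for s in set(scores)}
        wt = frequency_weights(counts, len(scores), "growth")
        vals = [wt.weights[s] for s in range(5)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        assert wt.weights[max(scores)] == pytest.approx(1.0)


class TestSeverityScaling:
    @pytest.mark.parametrize("w,s,s_max,expected", [
        (1.0, 4, 4, 1.0),
        (1.0, 2, 2, 1.0),
        (0.5, 1, 4, 0.125),
        (0.0, 0, 4, 0.0),
    ])
    def test_values(self, w, s, s_max, expected):
        assert severity_scaled_score(w, s, s_max) == pytest.approx(expected)

    def test_score_above_max_rejected(self):
        with pytest.raises(ValueError):
            severity_scaled_score(1.0, 5, 4)

    def test_strict_monotonicity_within_metric(self):
        # both levels observed: higher raw score must scale strictly higher
        wt = frequency_weights({1: 3, 3: 2}, 5, "growth")
        low = severity_scaled_score(wt.weights[1], 1, 4)
        high = severity_scaled_score(wt.weights[3], 3, 4)
        assert low < high


def _tables_for(scores_by_metric):
    """Weight tables from explicit per-metric count maps (weight 1 at max)."""
    out = {}
    for name, spec in METRICS.items():
        counts = scores_by_metric.get(name, {})
        if counts:
            n = sum(counts.values())
            out[name] = frequency_weights(counts, n, spec)
        else:
            out[name] = frequency_weights({1: 1}, 1, spec)  # unused levels
    return out


class TestIndividualCondition:
    def test_all_zero_metrics_score_zero(self):
        cs = individual_condition({}, _tables_for({}))
        assert cs.value == 0.0 and not cs.clamped

    def test_observed_extreme_positive(self):
        # growth capped at level 3 in the cohort, carrying full weight
        tables = _tables_for({"growth": {3: 5}})
        cs = individual_condition({"growth": 3}, tables)
        assert cs.value == pytest.approx(0.75)

    def test_observed_extreme_negative(self):
        tables = _tables_for({"tissue_loss": {4: 7}})
        cs = individual_condition({"tissue_loss": 4}, tables)
        assert cs.value == pytest.approx(-1.0)

    def test_sum_clamped_to_minus_one_with_components_recorded(self):
        tables = _tables_for({"tissue_loss": {4: 1}, "biofouling": {4: 1},
                              "orientation": {2: 1}})
        cs = individual_condition(
            {"tissue_loss": 4, "biofouling": 4, "orientation": 2}, tables)
        assert cs.value == -1.0 and cs.clamped
        assert sum(cs.components.values()) == pytest.approx(-3.0)

    def test_single_metric_never_clamps(self):
        tables = _tables_for({"biofouling": {2: 1, 4: 1}})
        cs = individual_condition({"biofouling": 4}, tables)
        assert not cs.clamped and -1 <= cs.value <= 0


class TestScoreTable:
    def test_values_in_range_and_t1_cohort_scored(self, t1_cohort):
        out = score_table(t1_cohort)
        assert len(out) == len(t1_cohort)
        assert out["condition"].between(-1, 1).all()

    def test_permutation_invariance(self, t1_cohort):
        a = score_table(t1_cohort).set_index("individual_id")["condition"]
        shuffled = t1_cohort.sample(frac=1, random_state=3).reset_index(drop=True)
        b = score_table(shuffled).set_index("individual_id")["condition"]
        assert a.sort_index().equals(b.sort_index())

    def test_per_site_pooling_differs_from_global(self):
        rows = (
            [{"site_id": "A", "growth": 1} for _ in range(9)]
            + [{"site_id": "A", "growth": 2}, {"site_id": "A", "growth": 3}]
            + [{"site_id": "B", "growth": 2} for _ in range(5)]
        )
        df = make_annotations(rows)
        glob = score_table(df, pooling="global")
        per = score_table(df, pooling="per_site")
        b_global = glob[glob["site_id"] == "B"]["condition"].iloc[0]
        b_per = per[per["site_id"] == "B"]["condition"].iloc[0]
        # within site B every growth score is 2, so per-site weight is 1
        assert b_per == pytest.approx(1.0 * 2 / 4)
        assert b_global != b_per


class TestFactorSummary:
    def test_single_individual_se_absent(self):
        df = score_table(make_annotations([{"tissue_loss": 2}]))
        out = factor_condition_summary(df, by="site_id")
        assert out["mean"].iloc[0] == pytest.approx(df["condition"].iloc[0])
        assert math.isnan(out["se"].iloc[0])

    def test_symmetric_scores_average_to_zero(self):
        df = score_table(make_annotations([{"growth": 0}, {"growth": 0}]))
        df.loc[:, "condition"] = [0.2, -0.2]
        out = factor_condition_summary(df, by="site_id")
        assert out["mean"].iloc[0] == pytest.approx(0.0)

    def test_hand_mean_and_se(self):
        df = score_table(make_annotations([{} for _ in range(4)]))
        df.loc[:, "condition"] = [-1.0, 0.0, 0.0, 0.0]
        out = factor_condition_summary(df, by="site_id")
        assert out["mean"].iloc[0] == pytest.approx(-0.25)
        assert out["se"].iloc[0] == pytest.approx(0.25)

    def test_zero_change_exclusion_mode(self):
        df = score_table(make_annotations([{}, {"tissue_loss": 1}]))
        full = factor_condition_summary(df, by="site_id")
        changed = factor_condition_summary(df, by="site_id",
                                           include_zero_change=False)
        assert full["n"].iloc[0] == 2 and changed["n"].iloc[0] == 1


def test_degenerate_metric_gets_zero_weight_table(t1_cohort):
    tables = build_weight_tables(t1_cohort)
    # no one fouled or toppled: their tables only ever multiply score zero
    assert all(v == 0.0 for v in tables["biofouling"].weights.values())
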