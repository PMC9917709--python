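"""Threshold screening, consensus, reduction accounting, change rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from musksynth import io_tables as io
from musksynth.screen import (build_screening_report, change_rate, consensus_sets,
                              evaluate_derivative, pairwise_relative_deviation,
                              reduction_percent, threshold_classify)


class TestThresholdClassify:
    def test_published_rf_table_yields_16(self):
        assert len(threshold_classify(io.load_table1())) == 16

    def test_published_gbc_table_yields_the_listed_10(self):
        got = threshold_classify(io.load_table3())
        assert got == {"D6", "D7", "D8", "D25", "D32", "D35", "D37", "D50", "D51", "D52"}

    def test_all_zero_scores_give_empty_set(self):
        st_ = io.ScoreTable("rf", {"D1": 0.0, "D2": 0.0})
        assert threshold_classify(st_) == set()

    def test_strict_vs_inclusive_boundary(self):
        st_ = io.ScoreTable("rf", {"D1": 0.5, "D2": 0.51})
        assert threshold_classify(st_) == {"D1", "D2"}
        assert threshold_classify(st_, inclusive=False) == {"D2"}


class TestConsensus:
    def test_published_tables_give_seven_member_consensus(self):
        sets = [threshold_classify(t) for t in
                (io.load_table1(), io.load_table2(), io.load_table3())]
        assert consensus_sets(sets) == {"D7", "D8", "D25", "D37", "D50", "D51", "D52"}

    def test_single_set_is_identity(self):
        assert consensus_sets([{"a", "b"}]) == {"a", "b"}

    def test_disjoint_sets_give_empty(self):
        assert consensus_sets([{"a"}, {"b"}]) == set()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sets(st.sampled_from("abcdefg")), min_size=1, max_size=5))
    def test_commutative_associative_idempotent(self, sets):
        assert consensus_sets(sets) == consensus_sets(sets[::-1])
        assert consensus_sets(sets + sets) == consensus_sets(sets)
        if len(sets) >= 2:
            left = consensus_sets([consensus_sets(sets[:1]), consensus_sets(sets[1:])])
            assert left == consensus_sets(sets)


class TestReductionPercent:
    @pytest.mark.parametrize("n,k,want", [(77, 16, 79.22), (10, 10, 0.0), (10, 0, 100.0)])
    def test_values(self, n, k, want):
        assert reduction_percent(n, k) == pytest.approx(want)

    def test_zero_unlabeled_rejected(self):
        with pytest.raises(ValueError):
            reduction_percent(0, 0)


class TestPairwiseDeviation:
    def test_hand_values_from_published_scores(self):
        assert pairwise_relative_deviation(0.61, 0.58, "first") == pytest.approx(4.92, abs=0.01)
        assert pairwise_relative_deviation(0.62, 0.56, "first") == pytest.approx(9.68, abs=0.01)

    def test_identical_scores_give_zero(self):
        for denom in ("first", "second", "mean"):
            assert pairwise_relative_deviation(0.4, 0.4, denom) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            pairwise_relative_deviation(0.0, 0.5, "first")


class TestChangeRate:
    @pytest.mark.parametrize("p,d,want", [
        (0.032, 8.387, 26109.38),   # LC50 improvement of the top HHCB derivative
        (105.461, 116.82, 10.77),   # odor-sensitivity gain of the MK derivative
        (111.766, 119.79, 7.18),    # odor-sensitivity gain of the HHCB derivative
        (3.0, 3.0, 0.0),
    ])
    def test_signed_percent_with_half_up_rounding(self, p, d, want):
        assert change_rate(p, d) == pytest.approx(want)

    def test_zero_parent_rejected(self):
        with pytest.raises(ValueError):
            change_rate(0.0, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=1e3),
           st.floats(min_value=0.01, max_value=1e3))
    def test_back_transform_consistency(self, p, d):
        r = change_rate(p, d, ndigits=None)
        assert p * (1.0 + r / 100.0) == pytest.approx(d, rel=1e-9)


class TestEvaluateDerivative:
    def test_odor_improvement_of_top_hhcb_derivative(self):
        table = io.load_table5()
        verdicts = evaluate_derivative(table, "D37")
        assert verdicts["OR5AN1"] == {"verdict": "improved", "change_rate": 7.18,
                                      "direction": "higher_better"}
        # docking to both hormone receptors decreased: abortion risk relieved
        assert verdicts["1A52"]["verdict"] == "improved"
        assert verdicts["1A28"]["verdict"] == "improved"

    def test_lower_keratin_binding_is_an_improvement(self):
        table = io.load_table5()
        verdicts = evaluate_derivative(table, "D25")
        assert verdicts["4ZRY"]["verdict"] == "improved"
        assert verdicts["4ZRY"]["change_rate"] < 0

    def test_identical_derivative_is_unchanged_everywhere(self):
        import pandas as pd

        rows = []
        for e in io.ENDPOINT_DIRECTIONS:
            rows.append({"molecule_id": "P1", "parent_id": "", "endpoint": e, "value": 2.0})
            rows.append({"molecule_id": "S1", "parent_id": "P1", "endpoint": e, "value": 2.0})
        table = io.EndpointTable(pd.DataFrame(rows))
        verdicts = evaluate_derivative(table, "S1")
        assert all(v["verdict"] == "unchanged" for v in verdicts.values())

    def test_missing_endpoint_yields_unknown(self):
        import pandas as pd

        rows = [{"molecule_id": "P1", "parent_id": "", "endpoint": "LC50", "value": 2.0},
                {"molecule_id": "S1", "parent_id": "P1", "endpoint": "LC50", "value": 3.0}]
        table = io.EndpointTable(pd.DataFrame(rows))
        verdicts = evaluate_derivative(table, "S1")
        assert verdicts["LC50"]["verdict"] == "improved"
        assert verdicts["1A52"]["verdict"] == "unknown"


class TestScreeningReport:
    def test_full_fixture_path_reproduces_published_accounting(self):
        report = build_screening_report(
            [io.load_table1(), io.load_table2(), io.load_table3()])
        assert {m: len(s) for m, s in report.per_model_sets.items()} == \
            {"rf": 16, "ert": 16, "gbc": 10}
        assert report.consensus == {"D7", "D8", "D25", "D37", "D50", "D51", "D52"}
        assert report.reduction_percent == pytest.approx(79.22)
        assert all(len(r) == 10 for r in report.rankings.values())
        assert report.to_dict()["consensus_size"] == 7

    def test_deviations_cover_rf_ert_overlap(self):
        report = build_screening_report([io.load_table1(), io.load_table2()])
        overlap = report.per_model_sets["rf"] & report.per_model_sets["ert"]
        assert set(report.deviations) == overlap
        # published D8 deviation between the two models
        assert report.deviations["D8"] == pytest.approx(4.92, abs=0.01)
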