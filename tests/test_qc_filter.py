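import numpy as np
import pandas as pd
import pytest

from fusioncurate import (
    FilterParams,
    FusionReference,
    expression_filter_fusion,
    filter_artifacts,
    filter_read_support,
    filter_readthroughs,
    final_reason,
    fusion_filtering_QC,
)
from fusioncurate.qc_filter import QC_STAGES


class TestArtifactFilter:
    @pytest.mark.parametrize(
        "token,removed",
        [
            ("GTEx_recurrent_STARF2019", True),
            ("DGD_PARALOGS", True),
            ("Greger_Normal", True),   # via the "Normal" alternative
            ("Babiceanu_Normal", True),
            ("BodyMap", True),
            ("ConjoinG", False),       # deliberately retained
            ("HGNC_GENEFAM", False),   # deliberately retained
            ("Mitelman", False),
        ],
    )
    def test_default_alternation(self, calls_factory, token, removed):
        calls = calls_factory([{"Gene1A": "A", "Gene1B": "B", "annots": token}])
        result = filter_artifacts(calls, FilterParams())
        assert (len(result.retained) == 0) is removed
        if removed:
            decision = result.decisions.iloc[0]
            assert decision["reason"] == "ARTIFACT_DB"
            assert decision["matched_token"] == token

    def test_malformed_regex_fails_before_filtering(self, calls_factory):
        calls = calls_factory([{"Gene1A": "A", "Gene1B": "B"}])
        with pytest.raises(ValueError, match="artifact_filter"):
            filter_artifacts(calls, FilterParams(artifact_filter="[unclosed"))


class TestReadthroughFilter:
    def test_rescued_by_mitelman_token(self, calls_factory):
        calls = calls_factory(
            [{"Gene1A": "P2RY8", "Gene1B": "CRLF2", "annots": "Mitelman,READTHRU"}]
        )
        result = filter_readthroughs(calls, FusionReference(), enabled=True)
        assert len(result.retained) == 1
        assert result.decisions.iloc[0]["reason"] == "READTHROUGH_RESCUED"

    def test_rescued_by_rescue_list(self, calls_factory):
        calls = calls_factory(
            [{"Gene1A": "P2RY8", "Gene1B": "CRLF2", "annots": "READTHRU"}]
        )
        rescue = FusionReference(rescue_names={"P2RY8--CRLF2"})
        result = filter_readthroughs(calls, rescue, enabled=True)
        assert len(result.retained) == 1

    def test_plain_readthrough_removed(self, calls_factory):
        calls = calls_factory([{"Gene1A": "G1", "Gene1B": "G2", "annots": "READTHRU"}])
        result = filter_readthroughs(calls, FusionReference(), enabled=True)
        assert len(result.retained) == 0
        assert result.decisions.iloc[0]["reason"] == "READTHROUGH"

    def test_disabled_retains_everything(self, calls_factory):
        calls = calls_factory([{"Gene1A": "G1", "Gene1B": "G2", "annots": "READTHRU"}])
        result = filter_readthroughs(calls, FusionReference(), enabled=False)
        assert len(result.retained) == 1

    @pytest.mark.parametrize("token", ["READTHRU", "read-through", "ReadThrough"])
    def test_token_spellings_detected(self, calls_factory, token):
        calls = calls_factory([{"Gene1A": "G1", "Gene1B": "G2", "annots": token}])
        result = filter_readthroughs(calls, FusionReference(), enabled=True)
        assert len(result.retained) == 0


class TestReadSupportFilter:
    @pytest.mark.parametrize(
        "junction,spanning,removed,reason",
        [
            (0, 5, True, "NO_JUNCTION_READS"),
            (2, 150, True, "SPANNING_DELTA"),   # delta 148 >= 100
            (2, 101, False, "PASS"),            # delta 99 < 100
            (1, 101, True, "SPANNING_DELTA"),   # delta 100 >= 100
            (1, 1, False, "PASS"),
        ],
    )
    def test_boundaries(self, calls_factory, junction, spanning, removed, reason):
        calls = calls_factory(
            [{"Gene1A": "A", "Gene1B": "B",
              "JunctionReadCount": junction, "SpanningFragCount": spanning}]
        )
        result = filter_read_support(calls, FilterParams())
        assert (len(result.retained) == 0) is removed
        assert result.decisions.iloc[0]["reason"] == reason

    def test_double_violation_records_both_conditions(self, calls_factory):
        calls = calls_factory(
            [{"Gene1A": "A", "Gene1B": "B",
              "JunctionReadCount": 0, "SpanningFragCount": 200}]
        )
        decision = filter_read_support(calls, FilterParams()).decisions.iloc[0]
        assert decision["reason"] == "NO_JUNCTION_READS"
        assert "junction=0" in decision["matched_token"]
        assert "delta=200" in decision["matched_token"]


class TestExpressionFilter:
    def test_both_partners_low_removed(self, calls_factory, expression_factory):
        calls = calls_factory([{"Gene1A": "A", "Gene1B": "B"}])
        expr = expression_factory({"A": 0.5, "B": 0.2})
        result = expression_filter_fusion(calls, expr, FilterParams())
        assert len(result.retained) == 0
        assert result.decisions.iloc[0]["reason"] == "NOT_EXPRESSED"

    def test_one_partner_expressed_retained(self, calls_factory, expression_factory):
        calls = calls_factory([{"Gene1A": "A", "Gene1B": "B"}])
        expr = expression_factory({"A": 0.5, "B": 5.0})
        assert len(expression_filter_fusion(calls, expr, FilterParams()).retained) == 1

    def test_missing_gene_treated_as_not_expressed(self, calls_factory,
                                                   expression_factory):
        calls = calls_factory([{"Gene1A": "ABSENT", "Gene1B": "B"}])
        expr = expression_factory({"B": 0.0})
        assert len(expression_filter_fusion(calls, expr, FilterParams()).retained) == 0

    def test_missing_sample_raises(self, calls_factory, expression_factory):
        calls = calls_factory([{"Gene1A": "A", "Gene1B": "B", "Sample": "S9"}])
        expr = expression_factory({"A": 1.0, "B": 1.0}, samples=("S1",))
        with pytest.raises(KeyError, match="S9"):
            expression_filter_fusion(calls, expr, FilterParams())


def _mixed_cohort(calls_factory):
    return calls_factory(
        [
            {"Gene1A": "A1", "Gene1B": "B1", "annots": "GTEx_recurrent_STARF2019",
             "JunctionReadCount": 0},
            {"Gene1A": "A2", "Gene1B": "B2", "annots": "READTHRU"},
            {"Gene1A": "A3", "Gene1B": "B3", "JunctionReadCount": 0},
            {"Gene1A": "A4", "Gene1B": "B4", "SpanningFragCount": 500},
            {"Gene1A": "LOW1", "Gene1B": "LOW2"},
            {"Gene1A": "A6", "Gene1B": "B6"},
            {"Gene1A": "P2RY8", "Gene1B": "CRLF2", "annots": "READTHRU,Mitelman"},
        ]
    )


def _mixed_expression(expression_factory):
    genes = {g: 10.0 for g in
             ["A1", "B1", "A2", "B2", "A3", "B3", "A4", "B4", "A6", "B6",
              "P2RY8", "CRLF2"]}
    genes.update({"LOW1": 0.1, "LOW2": 0.2})
    return genes


class TestCascade:
    def test_stage_order_and_single_removal(self, calls_factory, expression_factory):
        cohort = _mixed_cohort(calls_factory)
        expr = expression_factory(_mixed_expression(expression_factory))
        retained, ledger = fusion_filtering_QC(cohort, expr)
        reasons = final_reason(ledger)
        assert reasons[0] == "ARTIFACT_DB"  # artifact wins over junction==0
        assert reasons[1] == "READTHROUGH"
        assert reasons[2] == "NO_JUNCTION_READS"
        assert reasons[3] == "SPANNING_DELTA"
        assert reasons[4] == "NOT_EXPRESSED"
        assert reasons[5] == "PASS"
        assert reasons[6] == "READTHROUGH_RESCUED"
        assert set(retained.index) == {5, 6}

    def test_subset_and_count_conservation_per_stage(self, calls_factory,
                                                     expression_factory):
        cohort = _mixed_cohort(calls_factory)
        expr = expression_factory(_mixed_expression(expression_factory))
        _, ledger = fusion_filtering_QC(cohort, expr)
        seen = set(cohort.index)
        for stage in QC_STAGES:
            stage_rows = ledger[ledger["stage"] == stage]
            assert set(stage_rows["record_id"]) == seen
            removed = set(stage_rows.loc[~stage_rows["retained"], "record_id"])
            seen = seen - removed

    def test_order_robustness(self, calls_factory, expression_factory):
        cohort = _mixed_cohort(calls_factory)
        expr = expression_factory(_mixed_expression(expression_factory))
        baseline, _ = fusion_filtering_QC(cohort, expr)
        rng = np.random.default_rng(0)
        for _ in range(3):
            order = list(QC_STAGES)
            rng.shuffle(order)
            permuted, _ = fusion_filtering_QC(cohort, expr, stage_order=order)
            assert set(permuted.index) == set(baseline.index), order

    def test_threshold_monotonicity(self, calls_factory, expression_factory):
        rng = np.random.default_rng(1)
        rows = [
            {"Gene1A": f"A{i}", "Gene1B": f"B{i}",
             "JunctionReadCount": int(rng.integers(0, 5)),
             "SpanningFragCount": int(rng.integers(0, 300))}
            for i in range(40)
        ]
        cohort = calls_factory(rows)
        genes = {}
        for i in range(40):
            genes[f"A{i}"] = float(rng.uniform(0, 3))
            genes[f"B{i}"] = float(rng.uniform(0, 3))
        expr = expression_factory(genes)
        prev = None
        # raising spanning_delta_max or lowering expression_min only grows
        for delta_max, expr_min in [(50, 2.0), (100, 1.0), (200, 0.5)]:
            params = FilterParams(
                spanning_delta_max=delta_max, expression_min=expr_min
            )
            retained, _ = fusion_filtering_QC(cohort, expr, params)
            current = set(retained.index)
            if prev is not None:
                assert prev <= current
            prev = current

    def test_rescue_precedence_at_any_threshold(self, calls_factory):
        calls = calls_factory(
            [{"Gene1A": "P2RY8", "Gene1B": "CRLF2", "annots": "READTHRU,Mitelman"}]
        )
        for junction_min in (0, 1, 5):
            params = FilterParams(junction_min=junction_min)
            result = filter_readthroughs(
                calls, FusionReference(), enabled=params.readthrough_filter
            )
            assert result.decisions.iloc[0]["reason"] == "READTHROUGH_RESCUED"

    def test_expression_stage_skipped_without_matrix(self, calls_factory):
        cohort = calls_factory([{"Gene1A": "A", "Gene1B": "B"}])
        retained, ledger = fusion_filtering_QC(cohort, expr=None)
        assert len(retained) == 1
        assert "expression" not in set(ledger["stage"])
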