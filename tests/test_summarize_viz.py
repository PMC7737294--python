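import pandas as pd
import pytest

from fusioncurate import DomainInterval, GeneReference, build_domain_index
from fusioncurate.summarize_viz import (
    breakpoint_plot_data,
    plot_breakpoints,
    plot_recurrent_fusions,
    plot_recurrent_genes,
    plot_summary,
    read_exon_table,
    recurrent_fusion_table,
    recurrent_gene_table,
    render_report,
    summarize_cohort,
)

GENES = GeneReference(
    labels={
        "BRAF": {"oncogene", "kinase:Pkinase_Tyr", "biotype:protein_coding"},
        "KIAA1549": {"biotype:protein_coding"},
    }
)


class TestSummarizeCohort:
    def test_intra_vs_inter(self, calls_factory):
        final = calls_factory(
            [
                {"Gene1A": "A", "Gene1B": "B",
                 "LeftBreakpoint": "7:100", "RightBreakpoint": "7:900"},
                {"Gene1A": "C", "Gene1B": "D",
                 "LeftBreakpoint": "9:100", "RightBreakpoint": "22:900"},
            ]
        )
        final["group"] = "G1"
        summary = summarize_cohort(final, GENES)
        assert summary.chromosomal.loc["G1", "intra"] == 1
        assert summary.chromosomal.loc["G1", "inter"] == 1

    def test_classification_symmetric_under_breakpoint_swap(self, calls_factory):
        rows = [{"Gene1A": "A", "Gene1B": "B",
                 "LeftBreakpoint": "9:100", "RightBreakpoint": "22:900"}]
        swapped = [{"Gene1A": "B", "Gene1B": "A",
                    "LeftBreakpoint": "22:900", "RightBreakpoint": "9:100"}]
        s1 = summarize_cohort(calls_factory(rows), GENES)
        s2 = summarize_cohort(calls_factory(swapped), GENES)
        pd.testing.assert_frame_equal(s1.chromosomal, s2.chromosomal)

    def test_multi_category_gene_counted_in_each(self, calls_factory):
        final = calls_factory([{"Gene1A": "KIAA1549", "Gene1B": "BRAF"}])
        summary = summarize_cohort(final, GENES)
        categories = set(summary.oncogenic_counts["category"])
        assert {"oncogene", "kinase"} <= categories
        kinase = summary.kinase_group_counts
        assert kinase[kinase["partner"] == "3prime"]["n"].sum() == 1


def _final(calls_factory, rows, groups):
    df = calls_factory(rows)
    df["group"] = [groups[s] for s in df["Sample"]]
    return df


class TestRecurrenceTables:
    def test_distinct_patient_count(self, calls_factory):
        rows = [
            {"Sample": s, "Gene1A": "KIAA1549", "Gene1B": "BRAF"}
            for s in ("S1", "S2", "S3")
        ]
        final = _final(calls_factory, rows, {s: "LGG" for s in ("S1", "S2", "S3")})
        table = recurrent_fusion_table(final)
        assert table.iloc[0]["FusionName"] == "KIAA1549--BRAF"
        assert table.iloc[0]["count"] == 3

    def test_dominant_fusion_ranks_first(self, calls_factory):
        rows = [
            {"Sample": s, "Gene1A": "KIAA1549", "Gene1B": "BRAF"}
            for s in ("S1", "S2", "S3")
        ] + [{"Sample": "S1", "Gene1A": "X", "Gene1B": "Y"}]
        final = _final(
            calls_factory, rows, {s: "LGG" for s in ("S1", "S2", "S3")}
        )
        table = recurrent_fusion_table(final, top_n=2)
        assert list(table["FusionName"])[0] == "KIAA1549--BRAF"

    def test_ties_broken_lexicographically(self, calls_factory):
        rows = [
            {"Sample": "S1", "Gene1A": "B", "Gene1B": "C"},
            {"Sample": "S1", "Gene1A": "A", "Gene1B": "Z"},
        ]
        final = _final(calls_factory, rows, {"S1": "G"})
        table = recurrent_fusion_table(final)
        assert list(table["FusionName"]) == ["A--Z", "B--C"]

    def test_gene_counted_once_per_patient_across_positions(self, calls_factory):
        rows = [
            {"Sample": "S1", "Gene1A": "A", "Gene1B": "X"},
            {"Sample": "S1", "Gene1A": "Y", "Gene1B": "A"},
        ]
        final = _final(calls_factory, rows, {"S1": "G"})
        table = recurrent_gene_table(final)
        a_rows = table[table["gene"] == "A"]
        assert a_rows["count"].sum() == 1

    def test_group_sums_match_cohort_distinct_count(self, calls_factory):
        # groups partition samples, so per-group counts sum to the cohort count
        rows = [
            {"Sample": s, "Gene1A": "A", "Gene1B": "B"}
            for s in ("S1", "S2", "S3", "S4")
        ]
        final = _final(
            calls_factory, rows,
            {"S1": "G1", "S2": "G1", "S3": "G2", "S4": "G2"},
        )
        table = recurrent_fusion_table(final)
        assert table["count"].sum() == final["Sample"].nunique()


EXON_TSV = (
    "transcript_id\tgene_symbol\tchrom\texon_start\texon_end\tstrand\n"
    "TX1\tA\t7\t100\t200\t+\n"
    "TX1\tA\t7\t300\t400\t+\n"
    "TX1\tA\t7\t500\t600\t+\n"
    "TX2\tB\t9\t100\t200\t-\n"
)


class TestBreakpointPlotModel:
    @pytest.fixture
    def exon_table(self, tmp_path):
        path = tmp_path / "exons.tsv"
        path.write_text(EXON_TSV)
        return read_exon_table(path)

    def test_breakpoints_deduplicated(self, calls_factory, exon_table):
        final = calls_factory(
            [
                {"Gene1A": "A", "Gene1B": "B", "Caller": "STARFUSION",
                 "LeftBreakpoint": "7:350", "RightBreakpoint": "9:150"},
                {"Gene1A": "A", "Gene1B": "B", "Caller": "ARRIBA",
                 "LeftBreakpoint": "7:350", "RightBreakpoint": "9:150"},
                {"Gene1A": "A", "Gene1B": "B", "Sample": "S2",
                 "LeftBreakpoint": "7:550", "RightBreakpoint": "9:150"},
            ]
        )
        models = breakpoint_plot_data("A--B", final, exon_table)
        gene_a = models[0]
        assert gene_a.breakpoints == [350, 550]

    def test_exons_in_coordinate_order(self, calls_factory, exon_table):
        final = calls_factory(
            [{"Gene1A": "A", "Gene1B": "B",
              "LeftBreakpoint": "7:350", "RightBreakpoint": "9:150"}]
        )
        models = breakpoint_plot_data("A--B", final, exon_table)
        tx = models[0].transcripts[0]
        assert tx.exons == [(100, 200), (300, 400), (500, 600)]
        # minus-strand gene keeps genomic exon order, only the strand differs
        assert models[1].transcripts[0].strand == "-"

    def test_absent_fusion_gives_empty_model(self, calls_factory, exon_table,
                                             caplog):
        final = calls_factory([{"Gene1A": "A", "Gene1B": "B"}])
        assert breakpoint_plot_data("NO--PE", final, exon_table) == []

    def test_domains_attached(self, calls_factory, exon_table):
        index = build_domain_index(
            [DomainInterval("A", "PF1", "Dom", "7", 320, 380, "+", "TX1")]
        )
        final = calls_factory(
            [{"Gene1A": "A", "Gene1B": "B",
              "LeftBreakpoint": "7:350", "RightBreakpoint": "9:150"}]
        )
        models = breakpoint_plot_data("A--B", final, exon_table, index)
        assert models[0].transcripts[0].domains == [("Dom", 320, 380)]


class TestRenderingAndReport:
    def test_plots_write_files(self, calls_factory, tmp_path):
        final = calls_factory(
            [{"Gene1A": "KIAA1549", "Gene1B": "BRAF",
              "LeftBreakpoint": "7:100", "RightBreakpoint": "7:900"}]
        )
        final["group"] = "G1"
        summary = summarize_cohort(final, GENES)
        plot_summary(summary, tmp_path / "summary.png")
        plot_recurrent_fusions(recurrent_fusion_table(final), tmp_path / "rf.png")
        plot_recurrent_genes(recurrent_gene_table(final), tmp_path / "rg.png")
        for name in ("summary.png", "rf.png", "rg.png"):
            assert (tmp_path / name).stat().st_size > 0

    def test_breakpoint_plot_writes_file(self, calls_factory, tmp_path):
        exon_path = tmp_path / "exons.tsv"
        exon_path.write_text(EXON_TSV)
        final = calls_factory(
            [{"Gene1A": "A", "Gene1B": "B",
              "LeftBreakpoint": "7:350", "RightBreakpoint": "9:150"}]
        )
        models = breakpoint_plot_data("A--B", final, read_exon_table(exon_path))
        plot_breakpoints(models, tmp_path / "bp.png")
        assert (tmp_path / "bp.png").stat().st_size > 0

    def test_report_sections_and_sidecars(self, tmp_path):
        tables = {
            "final": pd.DataFrame({"FusionName": ["A--B"], "n": [1]}),
            "expression": None,  # upstream artifact missing
        }
        out = render_report(tmp_path / "report.html", tables, params={"seed": 1})
        text = out.read_text()
        assert "not computed" in text
        assert (tmp_path / "final.tsv").exists()
        assert not (tmp_path / "expression.tsv").exists()

    def test_report_body_is_deterministic(self, tmp_path):
        tables = {"t": pd.DataFrame({"a": [1, 2]})}
        p1 = render_report(tmp_path / "r1" / "report.html", tables, params={"x": 1})
        p2 = render_report(tmp_path / "r2" / "report.html", tables, params={"x": 1})
        assert p1.read_bytes() == p2.read_bytes()
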