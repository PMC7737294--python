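"""Cohort summaries, recurrence tables, breakpoint plot models and reporting.

All counting happens here on plain tables; the matplotlib figures and the
static HTML report are thin renderings of those tables and make no filtering
decisions of their own.  The report's reproducibility surface is its sidecar
TSVs, not figure pixels.
"""

from __future__ import annotations

import hashlib
import html
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from . import __version__ as _version
from .annotation import gene_labels
from .domain_retention import DomainIndex
from .io_standardization import GeneReference, parse_breakpoint

EXON_TABLE_COLUMNS = [
    "transcript_id",
    "gene_symbol",
    "chrom",
    "exon_start",
    "exon_end",
    "strand",
]

ONCO_CATEGORIES = ("oncogene", "tsg", "kinase", "cosmic", "tf_curated", "tf_predicted")


@dataclass
class CohortSummary:
    """Count tables behind the cohort summary figure."""

    chromosomal: pd.DataFrame  # group x {intra, inter}
    frame_counts: pd.DataFrame  # (Caller, Fusion_Type) -> n
    biotype_counts: pd.DataFrame  # biotype -> n genes
    kinase_group_counts: pd.DataFrame  # (partner, kinase group) -> n
    oncogenic_counts: pd.DataFrame  # (group, category) -> n


def summarize_cohort(final: pd.DataFrame, genes: GeneReference,
                     group_column: str = "group") -> CohortSummary:
    """Tally the distributions shown in the cohort summary.

    A fusion is intra-chromosomal iff both breakpoints share a chromosome.
    Biotype / kinase-group / oncogenic tallies count gene partners against the
    gene reference; a gene in several categories contributes to each.
    """
    rows = []
    for _, call in final.iterrows():
        left = parse_breakpoint(str(call["LeftBreakpoint"]))
        right = parse_breakpoint(str(call["RightBreakpoint"]))
        rows.append(
            {
                "group": call.get(group_column, "all"),
                "kind": "intra" if left.chrom == right.chrom else "inter",
            }
        )
    chrom_df = pd.DataFrame(rows, columns=["group", "kind"])
    chromosomal = (
        chrom_df.groupby(["group", "kind"]).size().unstack(fill_value=0)
        if len(chrom_df)
        else pd.DataFrame(columns=["intra", "inter"])
    )
    for col in ("intra", "inter"):
        if col not in chromosomal.columns:
            chromosomal[col] = 0
    chromosomal = chromosomal[["intra", "inter"]]

    frame_counts = (
        final.groupby(["Caller", "Fusion_Type"]).size().rename("n").reset_index()
    )

    biotype: dict[str, int] = {}
    kinase_rows = []
    onco_rows = []
    for _, call in final.iterrows():
        group = call.get(group_column, "all")
        for partner_col, position in (("Gene1A", "5prime"), ("Gene1B", "3prime")):
            labels = gene_labels(genes, call[partner_col])
            for lab in labels:
                if lab.startswith("biotype:"):
                    biotype[lab.split(":", 1)[1]] = (
                        biotype.get(lab.split(":", 1)[1], 0) + 1
                    )
                elif lab.startswith("kinase:"):
                    kinase_rows.append(
                        {"partner": position, "kinase_group": lab.split(":", 1)[1]}
                    )
            for category in ONCO_CATEGORIES:
                if category in labels:
                    onco_rows.append({"group": group, "category": category})
    biotype_counts = pd.DataFrame(
        sorted(biotype.items()), columns=["biotype", "n"]
    )
    kinase_group_counts = (
        pd.DataFrame(kinase_rows, columns=["partner", "kinase_group"])
        .groupby(["partner", "kinase_group"])
        .size()
        .rename("n")
        .reset_index()
    )
    oncogenic_counts = (
        pd.DataFrame(onco_rows, columns=["group", "category"])
        .groupby(["group", "category"])
        .size()
        .rename("n")
        .reset_index()
    )
    return CohortSummary(
        chromosomal=chromosomal,
        frame_counts=frame_counts,
        biotype_counts=biotype_counts,
        kinase_group_counts=kinase_group_counts,
        oncogenic_counts=oncogenic_counts,
    )


# ---------------------------------------------------------------------------
# Recurrence tables
# ---------------------------------------------------------------------------


def recurrent_fusion_table(final: pd.DataFrame, group_column: str = "group",
                           count_column: str = "Sample",
                           top_n: int = 10) -> pd.DataFrame:
    """Top recurrent fusions: distinct count_column values per (fusion, group).

    Ranked by total count across groups; ties broken lexicographically by
    fusion name so the table is deterministic.
    """
    if final.empty:
        return pd.DataFrame(columns=["FusionName", group_column, "count"])
    counts = (
        final.groupby(["FusionName", group_column])[count_column]
        .nunique()
        .rename("count")
        .reset_index()
    )
    totals = (
        counts.groupby("FusionName")["count"].sum().rename("total").reset_index()
    )
    totals = totals.sort_values(
        ["total", "FusionName"], ascending=[False, True], kind="stable"
    )
    top_names = totals["FusionName"].head(top_n)
    out = counts[counts["FusionName"].isin(top_names)].copy()
    order = {name: rank for rank, name in enumerate(top_names)}
    out["rank"] = out["FusionName"].map(order)
    out = out.sort_values(["rank", group_column], kind="stable").drop(columns="rank")
    return out.reset_index(drop=True)


def recurrent_gene_table(final: pd.DataFrame, group_column: str = "group",
                         count_column: str = "Sample",
                         top_n: int = 10) -> pd.DataFrame:
    """Top recurrently-fused genes, counting each count_column value once per gene.

    A gene appearing as 5' partner in one fusion and 3' in another within the
    same patient counts once for that patient.
    """
    if final.empty:
        return pd.DataFrame(columns=["gene", group_column, "count"])
    long = pd.concat(
        [
            final[[count_column, group_column, "Gene1A"]].rename(
                columns={"Gene1A": "gene"}
            ),
            final[[count_column, group_column, "Gene1B"]].rename(
                columns={"Gene1B": "gene"}
            ),
        ],
        ignore_index=True,
    ).drop_duplicates()
    counts = (
        long.groupby(["gene", group_column])[count_column]
        .nunique()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby("gene")["count"].sum().rename("total").reset_index()
    totals = totals.sort_values(
        ["total", "gene"], ascending=[False, True], kind="stable"
    )
    top = totals["gene"].head(top_n)
    out = counts[counts["gene"].isin(top)].copy()
    order = {name: rank for rank, name in enumerate(top)}
    out["rank"] = out["gene"].map(order)
    out = out.sort_values(["rank", group_column], kind="stable").drop(columns="rank")
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Breakpoint plot model
# ---------------------------------------------------------------------------


@dataclass
class TranscriptModel:
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # coordinate-ordered (start, end)
    domains: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class GenePlotModel:
    gene_symbol: str
    transcripts: list[TranscriptModel]
    breakpoints: list[int]  # deduplicated, sorted, pooled across callers


def read_exon_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EXON_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"exon table {path} missing column(s): {missing}")
    df["exon_start"] = df["exon_start"].astype(int)
    df["exon_end"] = df["exon_end"].astype(int)
    return df


def breakpoint_plot_data(fusion_name: str, final: pd.DataFrame,
                         exon_table: pd.DataFrame,
                         domain_index: DomainIndex | None = None
                         ) -> list[GenePlotModel]:
    """Per-gene transcript/exon/domain/breakpoint model for one fusion.

    Pools breakpoints across callers and samples, deduplicated.  Returns an
    empty list (with a warning) when the fusion is absent from the set.
    """
    subset = final[final["FusionName"] == fusion_name]
    if subset.empty:
        import logging

        logging.getLogger("fusioncurate").warning(
            "fusion %s not present in the prioritized set; empty plot model",
            fusion_name,
        )
        return []
    models = []
    for gene_col, bp_col in (("Gene1A", "LeftBreakpoint"), ("Gene1B", "RightBreakpoint")):
        gene = subset.iloc[0][gene_col]
        bps = sorted(
            {parse_breakpoint(str(bp)).pos for bp in subset[bp_col]}
        )
        transcripts = []
        gene_rows = exon_table[exon_table["gene_symbol"] == gene]
        for tx_id, tx_rows in gene_rows.groupby("transcript_id", sort=True):
            tx_rows = tx_rows.sort_values("exon_start")
            exons = list(zip(tx_rows["exon_start"], tx_rows["exon_end"]))
            domains = []
            if domain_index is not None:
                domains = [
                    (d.domain_name, d.start, d.end)
                    for d in domain_index.domains(gene)
                    if d.transcript_id in (None, tx_id)
                ]
            transcripts.append(
                TranscriptModel(
                    transcript_id=tx_id,
                    chrom=tx_rows.iloc[0]["chrom"],
                    strand=tx_rows.iloc[0]["strand"],
                    exons=exons,
                    domains=domains,
                )
            )
        models.append(
            GenePlotModel(gene_symbol=gene, transcripts=transcripts, breakpoints=bps)
        )
    return models


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def plot_summary(summary: CohortSummary, path: str | Path) -> None:
    """Render the four summary panels to one figure file."""
    fig, axes = plt.subplots(2, 2, figsize=(11, 8))
    if len(summary.chromosomal):
        summary.chromosomal.plot.barh(stacked=True, ax=axes[0, 0])
    axes[0, 0].set_title("Intra- vs inter-chromosomal fusions")
    if len(summary.frame_counts):
        pivot = summary.frame_counts.pivot(
            index="Caller", columns="Fusion_Type", values="n"
        ).fillna(0)
        pivot.plot.bar(ax=axes[0, 1])
    axes[0, 1].set_title("Frame by algorithm")
    if len(summary.kinase_group_counts):
        pivot = summary.kinase_group_counts.pivot(
            index="kinase_group", columns="partner", values="n"
        ).fillna(0)
        pivot.plot.bar(ax=axes[1, 0])
    axes[1, 0].set_title("Kinase groups by partner position")
    if len(summary.oncogenic_counts):
        pivot = summary.oncogenic_counts.pivot(
            index="category", columns="group", values="n"
        ).fillna(0)
        pivot.plot.bar(ax=axes[1, 1], legend=False)
    axes[1, 1].set_title("Oncogenic annotation by group")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _plot_recurrence(table: pd.DataFrame, key: str, group_column: str,
                     title: str, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 5))
    if len(table):
        pivot = table.pivot_table(
            index=key, columns=group_column, values="count", fill_value=0,
            aggfunc="sum",
        )
        totals = pivot.sum(axis=1).sort_values(ascending=True, kind="stable")
        pivot.loc[totals.index].plot.barh(stacked=True, ax=ax)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_recurrent_fusions(table: pd.DataFrame, path: str | Path,
                           group_column: str = "group") -> None:
    _plot_recurrence(table, "FusionName", group_column, "Recurrent fusions", path)


def plot_recurrent_genes(table: pd.DataFrame, path: str | Path,
                         group_column: str = "group") -> None:
    _plot_recurrence(table, "gene", group_column, "Recurrently-fused genes", path)


def plot_breakpoints(models: list[GenePlotModel], path: str | Path) -> None:
    """Exon boxes, domain boxes, strand arrows and breakpoint lines per gene."""
    n = max(len(models), 1)
    fig, axes = plt.subplots(n, 1, figsize=(10, 2.5 * n), squeeze=False)
    for ax, model in zip(axes[:, 0], models):
        for row, tx in enumerate(model.transcripts):
            for start, end in tx.exons:
                ax.add_patch(
                    plt.Rectangle((start, row - 0.2), end - start + 1, 0.4,
                                  color="black")
                )
            for name, start, end in tx.domains:
                ax.add_patch(
                    plt.Rectangle((start, row - 0.12), end - start + 1, 0.24,
                                  color="tab:orange", alpha=0.8)
                )
            if tx.exons:
                span_lo = min(s for s, _ in tx.exons)
                span_hi = max(e for _, e in tx.exons)
                ax.plot([span_lo, span_hi], [row, row], color="grey", lw=1, zorder=0)
                # strand arrow points along the transcription direction
                tip = span_hi if tx.strand == "+" else span_lo
                tail = span_lo if tx.strand == "+" else span_hi
                ax.annotate(
                    "", xy=(tip, row + 0.35), xytext=(tail, row + 0.35),
                    arrowprops={"arrowstyle": "->", "color": "grey"},
                )
        for bp in model.breakpoints:
            ax.axvline(bp, color="red", linestyle=":", lw=1)
        ax.set_yticks(range(len(model.transcripts)))
        ax.set_yticklabels([tx.transcript_id for tx in model.transcripts])
        ax.set_title(model.gene_symbol)
        ax.relim()
        ax.autoscale_view()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Static report
# ---------------------------------------------------------------------------

_REPORT_TEMPLATE = """<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>fusioncurate report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #999; padding: 2px 8px; }}
</style></head>
<body>
<h1>Fusion prioritization report</h1>
<p>fusioncurate version {version}</p>
<h2>Parameters</h2>
{params}
<h2>Input checksums</h2>
{checksums}
{sections}
</body></html>
"""


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def render_report(
    out_path: str | Path,
    tables: dict[str, pd.DataFrame | None],
    params: dict[str, object] | None = None,
    input_paths: list[str | Path] | None = None,
    figures: list[str | Path] | None = None,
) -> Path:
    """Write a self-contained static HTML report plus TSV sidecars.

    Each named table is embedded as HTML and written next to the report as
    ``<name>.tsv``; a table given as None renders an explicit "not computed"
    block.  The body is byte-stable for fixed inputs (no timestamps).
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)

    param_html = (
        "<table>"
        + "".join(
            f"<tr><th>{html.escape(str(k))}</th><td>{html.escape(str(v))}</td></tr>"
            for k, v in sorted((params or {}).items())
        )
        + "</table>"
    )
    checksum_html = (
        "<table>"
        + "".join(
            f"<tr><th>{html.escape(Path(p).name)}</th>"
            f"<td>{_sha256(Path(p))}</td></tr>"
            for p in (input_paths or [])
        )
        + "</table>"
    )
    sections = []
    for name, table in tables.items():
        sections.append(f"<h2>{html.escape(name)}</h2>")
        if table is None:
            sections.append("<p><em>not computed</em></p>")
            continue
        sidecar = out_path.parent / f"{name}.tsv"
        table.to_csv(sidecar, sep="\t", index=False, na_rep="NA")
        sections.append(table.to_html(index=False, border=0))
    if figures:
        sections.append("<h2>Figures</h2>")
        for fig in figures:
            sections.append(f'<p><img src="{html.escape(Path(fig).name)}"></p>')

    out_path.write_text(
        _REPORT_TEMPLATE.format(
            version=_version,
            params=param_html,
            checksums=checksum_html,
            sections="\n".join(sections),
        )
    )
    return out_path
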