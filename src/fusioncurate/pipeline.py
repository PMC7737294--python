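"""End-to-end composition: standardize -> QC -> annotate -> prioritize.

The building blocks live in their own modules; this module wires them
together for the common cases — a whole cohort directory (as produced by the
synthetic generator or by a caller workflow laid out the same way) and the
single-sample run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .annotation import annotate_fusion_calls
from .domain_retention import DomainIndex, annotate_domain_retention, read_domain_table
from .io_standardization import (
    ExpressionMatrix,
    FusionReference,
    GeneReference,
    fusion_standardization,
    merge_callers,
    read_arriba,
    read_expression_matrix,
    read_fusion_reference,
    read_gene_reference,
    read_starfusion,
    write_standardized,
)
from .project_filter import CohortConfig, prioritize
from .qc_filter import FilterParams, final_reason, fusion_filtering_QC


@dataclass
class PipelineResult:
    standardized: pd.DataFrame      # merged standardized cohort (all records)
    ledger: pd.DataFrame            # QC decision ledger
    qc_reasons: pd.Series           # terminal QC reason per record id
    qc_pass: pd.DataFrame           # records surviving QC
    annotated: pd.DataFrame         # qc_pass + annotation columns
    final: pd.DataFrame             # putative oncogenic set with origin
    domain_table: pd.DataFrame | None = None  # long-format domain retention


def standardize_sample(
    sample_id: str,
    starfusion_path: str | Path | None = None,
    arriba_path: str | Path | None = None,
) -> pd.DataFrame:
    """Standardize one sample's caller outputs into one table."""
    records = []
    if starfusion_path is not None:
        records.extend(read_starfusion(starfusion_path, sample_id))
    if arriba_path is not None:
        records.extend(read_arriba(arriba_path, sample_id))
    return fusion_standardization(records)


def run_cohort_pipeline(
    standardized: pd.DataFrame,
    expr: ExpressionMatrix | None,
    genes: GeneReference,
    fusions: FusionReference | None,
    metadata: pd.DataFrame,
    params: FilterParams | None = None,
    config: CohortConfig | None = None,
    domain_index: DomainIndex | None = None,
) -> PipelineResult:
    """QC-filter, annotate and prioritize a merged standardized cohort."""
    params = params or FilterParams()
    config = config or CohortConfig()
    qc_pass, ledger = fusion_filtering_QC(
        standardized, expr=expr, params=params, rescue=fusions
    )
    reasons = final_reason(ledger) if len(ledger) else pd.Series(dtype=object)
    annotated = annotate_fusion_calls(qc_pass, genes, fusions, check_reciprocal=True)
    final = prioritize(annotated, metadata, config)
    domain_table = None
    if domain_index is not None:
        final, domain_table = annotate_domain_retention(final, domain_index)
    return PipelineResult(
        standardized=standardized,
        ledger=ledger,
        qc_reasons=reasons,
        qc_pass=qc_pass,
        annotated=annotated,
        final=final,
        domain_table=domain_table,
    )


def run_from_directory(
    cohort_dir: str | Path,
    params: FilterParams | None = None,
    config: CohortConfig | None = None,
    with_domains: bool = True,
) -> PipelineResult:
    """Run the full pipeline on a cohort directory.

    Expects, per sample, ``<sample>.starfusion.tsv`` and/or
    ``<sample>.arriba.tsv``, plus ``expression.tsv``, ``genelistreference.tsv``,
    ``fusionreference.tsv``, ``rescue_list.tsv``, ``metadata.tsv`` and
    optionally ``domains.tsv`` — the layout written by
    :func:`fusioncurate.synthetic_fixtures.generate_cohort`.
    """
    cohort_dir = Path(cohort_dir)
    sample_ids = sorted(
        {p.name.rsplit(".", 2)[0] for p in cohort_dir.glob("*.starfusion.tsv")}
        | {p.name.rsplit(".", 2)[0] for p in cohort_dir.glob("*.arriba.tsv")}
    )
    tables = []
    for sample in sample_ids:
        sf = cohort_dir / f"{sample}.starfusion.tsv"
        ar = cohort_dir / f"{sample}.arriba.tsv"
        tables.append(
            standardize_sample(
                sample,
                starfusion_path=sf if sf.exists() else None,
                arriba_path=ar if ar.exists() else None,
            )
        )
    standardized = merge_callers(tables)

    expr = read_expression_matrix(cohort_dir / "expression.tsv")
    genes = read_gene_reference(cohort_dir / "genelistreference.tsv")
    rescue_path = cohort_dir / "rescue_list.tsv"
    fusions = read_fusion_reference(
        cohort_dir / "fusionreference.tsv",
        rescue_path=rescue_path if rescue_path.exists() else None,
    )
    metadata = pd.read_csv(cohort_dir / "metadata.tsv", sep="\t", dtype=str)
    domain_path = cohort_dir / "domains.tsv"
    domain_index = (
        read_domain_table(domain_path)
        if with_domains and domain_path.exists()
        else None
    )
    return run_cohort_pipeline(
        standardized, expr, genes, fusions, metadata,
        params=params, config=config, domain_index=domain_index,
    )


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the standard output tables; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "standardized": out / "StandardizedFusionCalls.tsv",
        "ledger": out / "FilterLedger.tsv",
        "qc_pass": out / "FilteredFusionCalls.tsv",
        "final": out / "PutativeDriverFusions.tsv",
    }
    write_standardized(result.standardized, paths["standardized"])
    result.ledger.to_csv(paths["ledger"], sep="\t", index=False, na_rep="NA")
    write_standardized(result.qc_pass, paths["qc_pass"])
    result.final.to_csv(paths["final"], sep="\t", index=False, na_rep="NA")
    if result.domain_table is not None:
        paths["domains"] = out / "DomainRetention.tsv"
        result.domain_table.to_csv(
            paths["domains"], sep="\t", index=False, na_rep="NA"
        )
    return paths


def single_sample_run(
    sample_id: str,
    starfusion_path: str | Path | None,
    arriba_path: str | Path | None,
    expr: ExpressionMatrix | None,
    genes: GeneReference,
    fusions: FusionReference | None = None,
    params: FilterParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize, QC-filter and annotate one sample's calls.

    Returns (annotated filtered calls, QC ledger).  Project-level
    prioritization needs a cohort and is not applied here.
    """
    standardized = standardize_sample(sample_id, starfusion_path, arriba_path)
    qc_pass, ledger = fusion_filtering_QC(
        standardized, expr=expr, params=params or FilterParams(), rescue=fusions
    )
    annotated = annotate_fusion_calls(qc_pass, genes, fusions, check_reciprocal=True)
    return annotated, ledger
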