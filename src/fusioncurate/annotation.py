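"""Gene-list, fusion-reference, reciprocality and z-score annotation.

Annotation is pure decoration: it never changes the number of records or any
QC field, it only appends columns.  Partner genes are labeled from user gene
lists (oncogene, tumor suppressor, kinase, transcription factor, COSMIC),
fusion names are looked up in a known-fusion reference (e.g. TCGA), and
reciprocal events (A--B and B--A in the same sample) are flagged.

The optional z-score annotation compares the expression of each fused gene
against a reference distribution (GTEx-like matrix or the cohort itself):

    z(g, s) = (expr(g, s) - median_ref(g)) / sd_ref(g)

with sd the sample standard deviation (n-1 denominator).  |z| above the
cutoff (default 2) flags the gene as differentially expressed in either
direction.  Genes with a degenerate reference (sd 0) are left unflagged and
logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_standardization import (
    ExpressionMatrix,
    FusionReference,
    GeneReference,
)

logger = logging.getLogger("fusioncurate")

#: Labels that mark a gene partner as cancer-relevant for driver prioritization.
DRIVER_LABELS = frozenset(
    {"oncogene", "tsg", "kinase", "tf_curated", "tf_predicted", "cosmic"}
)

ANNOTATION_COLUMNS = [
    "Gene1A_anno",
    "Gene1B_anno",
    "Fusion_anno",
    "reciprocal_exists",
]


def _label_string(labels: set[str]) -> str:
    return ",".join(sorted(labels))


def gene_labels(ref: GeneReference, gene: str) -> set[str]:
    """All labels for a gene; kinase:<group> labels also imply bare 'kinase'."""
    labels = set(ref.get(gene))
    if any(lab.startswith("kinase:") for lab in labels):
        labels.add("kinase")
    return labels


def annotate_fusion_calls(
    calls: pd.DataFrame,
    genes: GeneReference,
    fusions: FusionReference | None = None,
    check_reciprocal: bool = True,
) -> pd.DataFrame:
    """Append partner labels, fusion-reference tags and reciprocality flags.

    ``Gene1A_anno``/``Gene1B_anno`` hold the comma-joined labels of each
    partner (empty for unknown genes); ``Fusion_anno`` holds the source tags
    of the fusion name (e.g. TCGA); ``reciprocal_exists`` is true iff the same
    sample also contains the gene-swapped fusion.
    """
    out = calls.copy()
    out["Gene1A_anno"] = [
        _label_string(gene_labels(genes, g)) for g in out["Gene1A"]
    ]
    out["Gene1B_anno"] = [
        _label_string(gene_labels(genes, g)) for g in out["Gene1B"]
    ]
    if fusions is not None:
        out["Fusion_anno"] = [
            _label_string(fusions.get_tags(name)) for name in out["FusionName"]
        ]
    else:
        out["Fusion_anno"] = ""

    if check_reciprocal:
        by_sample: dict[str, set[str]] = {}
        for sample, name in zip(out["Sample"], out["FusionName"]):
            by_sample.setdefault(sample, set()).add(name)
        swapped = [
            f"{b}--{a}" in by_sample.get(sample, set())
            for sample, a, b in zip(out["Sample"], out["Gene1A"], out["Gene1B"])
        ]
        out["reciprocal_exists"] = swapped
    else:
        out["reciprocal_exists"] = pd.NA
    return out


def zscore_gene(
    expr_value: float | None,
    reference_values: np.ndarray,
) -> float:
    """z of one expression value against a reference: (x - median) / sd.

    Returns NaN when the value is missing, the reference is empty/degenerate
    (fewer than 2 values or sd 0).
    """
    if expr_value is None:
        return float("nan")
    ref = np.asarray(reference_values, dtype=float)
    ref = ref[~np.isnan(ref)]
    if ref.size < 2:
        return float("nan")
    sd = float(np.std(ref, ddof=1))
    if sd == 0.0:
        return float("nan")
    return (float(expr_value) - float(np.median(ref))) / sd


def zscored_annotation(
    calls: pd.DataFrame,
    expr: ExpressionMatrix,
    reference: ExpressionMatrix,
    zscore_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Append per-partner expression z-scores and differential-expression flags.

    For each fused gene g in sample s, z = (expr(g,s) - median_ref(g)) /
    sd_ref(g) over the reference matrix rows; |z| > cutoff flags the gene
    (two-sided, over- or under-expression).  Genes absent from the reference
    or with sd 0 get an undefined z and no flag.
    """
    out = calls.copy()
    ref_values = reference.values

    def z_for(gene: str, sample: str) -> float:
        if gene not in ref_values.index:
            return float("nan")
        value = expr.get(gene, sample) if sample in expr.samples else None
        z = zscore_gene(value, ref_values.loc[gene].to_numpy())
        return z

    z_a, z_b = [], []
    for i in out.index:
        sample = out.at[i, "Sample"]
        za = z_for(out.at[i, "Gene1A"], sample)
        zb = z_for(out.at[i, "Gene1B"], sample)
        z_a.append(za)
        z_b.append(zb)
    out["zscore_Gene1A"] = z_a
    out["zscore_Gene1B"] = z_b
    out["note_expression_Gene1A"] = [
        bool(abs(z) > zscore_cutoff) if not np.isnan(z) else False for z in z_a
    ]
    out["note_expression_Gene1B"] = [
        bool(abs(z) > zscore_cutoff) if not np.isnan(z) else False for z in z_b
    ]
    n_degenerate = sum(np.isnan(z) for z in z_a) + sum(np.isnan(z) for z in z_b)
    if n_degenerate:
        logger.info(
            "z-score annotation: %d partner lookups had no usable reference "
            "distribution (gene absent or sd = 0); left unflagged",
            n_degenerate,
        )
    return out


def has_driver_annotation(row: pd.Series) -> bool:
    """True when either partner carries a driver label or the fusion is known."""
    for col in ("Gene1A_anno", "Gene1B_anno"):
        labels = {
            lab.split(":")[0] for lab in str(row.get(col, "")).split(",") if lab
        }
        if labels & DRIVER_LABELS:
            return True
    return bool(str(row.get("Fusion_anno", "")).strip())
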