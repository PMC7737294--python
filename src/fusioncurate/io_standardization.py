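"""Read caller-native fusion TSVs and emit the standardized call schema.

STAR-Fusion and Arriba report chimeric transcripts in different dialects:
column names, breakpoint encodings, read-support accounting and reading-frame
vocabularies all differ.  Everything downstream (QC filtering, annotation,
cohort prioritization) operates on one flat table, so this module is the only
place caller dialects are known.

Both callers must have been post-annotated with FusionAnnotator so that every
row carries an ``annots`` column; those free-text tag lists are parsed here
into clean token sets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fusioncurate")

# ---------------------------------------------------------------------------
# Schema constants
# ---------------------------------------------------------------------------

#: Column order of the standardized fusion-call table.
STANDARD_COLUMNS = [
    "Sample",
    "FusionName",
    "Gene1A",
    "Gene2A",
    "Gene1B",
    "Gene2B",
    "LeftBreakpoint",
    "RightBreakpoint",
    "LeftStrand",
    "RightStrand",
    "Fusion_Type",
    "Caller",
    "JunctionReadCount",
    "SpanningFragCount",
    "Confidence",
    "annots",
]

FUSION_TYPES = ("in-frame", "frameshift", "other")

STARFUSION_REQUIRED = [
    "FusionName",
    "JunctionReadCount",
    "SpanningFragCount",
    "LeftBreakpoint",
    "RightBreakpoint",
    "PROT_FUSION_TYPE",
    "annots",
]

ARRIBA_REQUIRED = [
    "gene1",
    "gene2",
    "breakpoint1",
    "breakpoint2",
    "split_reads1",
    "split_reads2",
    "discordant_mates",
    "reading_frame",
    "confidence",
    "annots",
]

NA_VALUES = ["NA", ""]


class Caller(str, Enum):
    STARFUSION = "STARFUSION"
    ARRIBA = "ARRIBA"


class SchemaError(ValueError):
    """An input table is missing a required column."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Breakpoint:
    """A 1-based genomic breakpoint; ``chrom`` is stored without a chr prefix."""

    chrom: str
    pos: int
    strand: str = "unknown"  # "+", "-" or "unknown"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("breakpoint chromosome must be non-empty")
        if self.pos < 1:
            raise ValueError(f"breakpoint position must be >= 1, got {self.pos}")

    def __str__(self) -> str:  # "chrom:pos" — strand kept in its own column
        return f"{self.chrom}:{self.pos}"


@dataclass
class RawCallerRecord:
    """One native caller row, column values kept verbatim as strings."""

    caller: Caller
    source_columns: dict[str, str]
    sample_id: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression (FPKM or TPM), indexed by gene symbol."""

    values: pd.DataFrame  # index = GeneSymbol, columns = samples
    unit: str = "FPKM"

    def get(self, gene: str, sample: str) -> float | None:
        """Expression of ``gene`` in ``sample``; None when the gene is absent.

        A missing sample column is an error (the caller asked about a sample
        the matrix does not cover), a missing gene is an explicit None so that
        filters can apply their own not-expressed policy.
        """
        if sample not in self.values.columns:
            raise KeyError(f"sample {sample!r} absent from expression matrix")
        if gene not in self.values.index:
            return None
        return float(self.values.at[gene, sample])

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneReference:
    """Gene symbol -> set of labels (oncogene, tsg, kinase:<group>, ...)."""

    labels: dict[str, set[str]] = field(default_factory=dict)

    def get(self, gene: str) -> set[str]:
        return self.labels.get(gene, set())


@dataclass
class FusionReference:
    """Known-fusion lookup: source tags per fusion name plus a rescue list.

    ``tags`` holds annotation sources (e.g. TCGA) used for driver
    prioritization; ``rescue_names`` holds fusion names treated as known
    oncogenic (Mitelman-style) for read-through rescue.  Names are ordered:
    ``A--B`` is distinct from ``B--A``.
    """

    tags: dict[str, set[str]] = field(default_factory=dict)
    rescue_names: set[str] = field(default_factory=set)

    def get_tags(self, fusion_name: str) -> set[str]:
        return self.tags.get(fusion_name, set())


# ---------------------------------------------------------------------------
# annots parsing
# ---------------------------------------------------------------------------

_ANNOT_STRIP = re.compile(r'[\[\]"\']')


def parse_annots(raw: object) -> frozenset[str]:
    """Parse a FusionAnnotator ``annots`` cell into a clean token set.

    The raw cell looks like ``["GTEx_recurrent_STARF2019","INTRACHROMOSOMAL"]``
    possibly with several bracketed groups joined by semicolons.  Brackets and
    quotes are stripped, tokens split on commas/semicolons, whitespace trimmed,
    duplicates collapsed.  Empty or missing cells give an empty set.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return frozenset()
    text = _ANNOT_STRIP.sub("", str(raw))
    tokens = (tok.strip() for tok in re.split(r"[,;]", text))
    return frozenset(tok for tok in tokens if tok)


def format_annots(tokens: Iterable[str]) -> str:
    """Serialize a token set for the TSV writer (sorted, comma-joined)."""
    return ",".join(sorted(tokens))


# ---------------------------------------------------------------------------
# Caller readers
# ---------------------------------------------------------------------------


def _read_caller_tsv(path: str | Path, required: Sequence[str], caller: Caller,
                     sample_id: str) -> list[RawCallerRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    # both callers prefix their first header field with '#'
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{caller.value} file {path} is missing required column(s): "
            + ", ".join(missing)
        )
    return [
        RawCallerRecord(caller=caller, source_columns=row, sample_id=sample_id)
        for row in df.to_dict(orient="records")
    ]


def read_starfusion(path: str | Path, sample_id: str) -> list[RawCallerRecord]:
    """Read a ``star-fusion.fusion_predictions.tsv``-dialect file.

    The header may name the first column ``#FusionName`` or ``FusionName``.
    An ``annots`` column (FusionAnnotator output) is required.  A file with
    only a header yields an empty list.
    """
    return _read_caller_tsv(path, STARFUSION_REQUIRED, Caller.STARFUSION, sample_id)


def read_arriba(path: str | Path, sample_id: str) -> list[RawCallerRecord]:
    """Read an Arriba ``fusions.tsv``-dialect file with an appended annots column.

    Breakpoint strings ("chrom:pos") are retained verbatim; parsing happens in
    :func:`fusion_standardization`.
    """
    return _read_caller_tsv(path, ARRIBA_REQUIRED, Caller.ARRIBA, sample_id)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

_STARFUSION_FRAME = {"INFRAME": "in-frame", "FRAMESHIFT": "frameshift"}
_ARRIBA_FRAME = {"in-frame": "in-frame", "out-of-frame": "frameshift"}

_DISTANCE_SUFFIX = re.compile(r"\(\d+\)$")


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def parse_breakpoint(text: str, strand_hint: str | None = None) -> Breakpoint:
    """Parse ``chr7:140787584:-`` or ``7:140787584`` into a Breakpoint."""
    parts = text.strip().split(":")
    if len(parts) < 2:
        raise ValueError(f"unparseable breakpoint {text!r}")
    chrom = _norm_chrom(parts[0])
    pos = int(parts[1])
    strand = parts[2] if len(parts) > 2 and parts[2] in ("+", "-") else None
    if strand is None and strand_hint in ("+", "-"):
        strand = strand_hint
    return Breakpoint(chrom=chrom, pos=pos, strand=strand or "unknown")


def _split_gene_cell(cell: str) -> tuple[str, str | None]:
    """Split a multi-gene Arriba cell ("A,B" or "A(1234),B") into (first, second)."""
    symbols = [
        _DISTANCE_SUFFIX.sub("", part.strip())
        for part in cell.split(",")
        if part.strip()
    ]
    first = symbols[0] if symbols else ""
    second = symbols[1] if len(symbols) > 1 else None
    return first, second


def _map_frame(value: str, mapping: Mapping[str, str], caller: Caller) -> str:
    mapped = mapping.get(value.strip())
    if mapped is None:
        if value.strip() not in (".", "", "NA"):
            logger.warning(
                "%s reading-frame value %r not in the standard vocabulary; "
                "recorded as 'other'", caller.value, value,
            )
        return "other"
    return mapped


def _standardize_starfusion(rec: RawCallerRecord) -> dict[str, object]:
    cols = rec.source_columns
    gene1a, gene1b = cols["FusionName"].split("--", 1)
    left = parse_breakpoint(cols["LeftBreakpoint"])
    right = parse_breakpoint(cols["RightBreakpoint"])
    return {
        "Sample": rec.sample_id,
        "FusionName": f"{gene1a}--{gene1b}",
        "Gene1A": gene1a,
        "Gene2A": None,
        "Gene1B": gene1b,
        "Gene2B": None,
        "LeftBreakpoint": str(left),
        "RightBreakpoint": str(right),
        "LeftStrand": left.strand,
        "RightStrand": right.strand,
        "Fusion_Type": _map_frame(cols["PROT_FUSION_TYPE"], _STARFUSION_FRAME,
                                  rec.caller),
        "Caller": rec.caller.value,
        "JunctionReadCount": int(cols["JunctionReadCount"]),
        "SpanningFragCount": int(cols["SpanningFragCount"]),
        "Confidence": None,
        "annots": format_annots(parse_annots(cols["annots"])),
    }


def _standardize_arriba(rec: RawCallerRecord) -> dict[str, object]:
    cols = rec.source_columns
    gene1a, gene2a = _split_gene_cell(cols["gene1"])
    gene1b, gene2b = _split_gene_cell(cols["gene2"])
    # Arriba breakpoint strings carry no per-breakpoint strand; use the gene
    # strand columns when present ("strand1(gene/fusion)" -> "+/+"), otherwise
    # record unknown rather than inventing an orientation.
    strand1 = _arriba_strand(cols.get("strand1(gene/fusion)"))
    strand2 = _arriba_strand(cols.get("strand2(gene/fusion)"))
    left = parse_breakpoint(cols["breakpoint1"], strand_hint=strand1)
    right = parse_breakpoint(cols["breakpoint2"], strand_hint=strand2)
    confidence = cols.get("confidence", "").strip() or None
    return {
        "Sample": rec.sample_id,
        "FusionName": f"{gene1a}--{gene1b}",
        "Gene1A": gene1a,
        "Gene2A": gene2a,
        "Gene1B": gene1b,
        "Gene2B": gene2b,
        "LeftBreakpoint": str(left),
        "RightBreakpoint": str(right),
        "LeftStrand": left.strand,
        "RightStrand": right.strand,
        "Fusion_Type": _map_frame(cols["reading_frame"], _ARRIBA_FRAME, rec.caller),
        "Caller": rec.caller.value,
        "JunctionReadCount": int(cols["split_reads1"]) + int(cols["split_reads2"]),
        "SpanningFragCount": int(cols["discordant_mates"]),
        "Confidence": confidence,
        "annots": format_annots(parse_annots(cols["annots"])),
    }


def _arriba_strand(cell: str | None) -> str | None:
    if not cell:
        return None
    # "strand(gene)/strand(fusion)"; the fusion strand is authoritative
    fusion_strand = cell.split("/")[-1].strip()
    return fusion_strand if fusion_strand in ("+", "-") else None


def fusion_standardization(records: Iterable[RawCallerRecord]) -> pd.DataFrame:
    """Convert raw caller records to the standardized schema.

    Every input record maps to exactly one output row — no silent drops.
    Frame vocabularies are unified to in-frame / frameshift / other; Arriba
    junction support is the sum of split reads at both breakpoints and its
    spanning support is the discordant-mate count.
    """
    rows = []
    for rec in records:
        if rec.caller is Caller.STARFUSION:
            rows.append(_standardize_starfusion(rec))
        elif rec.caller is Caller.ARRIBA:
            rows.append(_standardize_arriba(rec))
        else:  # pragma: no cover - enum is closed
            raise ValueError(f"unknown caller {rec.caller}")
    df = pd.DataFrame(rows, columns=STANDARD_COLUMNS)
    return _finalize(df)


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("JunctionReadCount", "SpanningFragCount"):
        df[col] = df[col].astype("int64")
    df.index = pd.RangeIndex(len(df))
    return df


def spanning_delta(df: pd.DataFrame) -> pd.Series:
    """spanningDelta = SpanningFragCount - JunctionReadCount."""
    return df["SpanningFragCount"] - df["JunctionReadCount"]


def merge_callers(call_sets: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate standardized tables from several callers/samples.

    Every record is preserved (duplicate rows included — deduplication is an
    explicit later step), ordering is the stable sort on
    (Sample, FusionName, Caller).
    """
    if not call_sets:
        return pd.DataFrame(columns=STANDARD_COLUMNS)
    merged = pd.concat(list(call_sets), ignore_index=True)
    merged = merged.sort_values(
        ["Sample", "FusionName", "Caller"], kind="stable"
    ).reset_index(drop=True)
    return _finalize(merged)


# ---------------------------------------------------------------------------
# Standardized-table round trip
# ---------------------------------------------------------------------------


def write_standardized(df: pd.DataFrame, path: str | Path) -> None:
    """Write a standardized table as TSV (missing values emitted as "NA")."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_standardized(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_standardized`, field-for-field."""
    df = pd.read_csv(
        path, sep="\t", dtype=str, na_values=NA_VALUES, keep_default_na=False
    )
    missing = [c for c in STANDARD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"standardized table {path} is missing column(s): " + ", ".join(missing)
        )
    df["Gene2A"] = df["Gene2A"].where(df["Gene2A"].notna(), None)
    df["Gene2B"] = df["Gene2B"].where(df["Gene2B"].notna(), None)
    df["Confidence"] = df["Confidence"].where(df["Confidence"].notna(), None)
    df["annots"] = df["annots"].fillna("")
    return _finalize(df)


# ---------------------------------------------------------------------------
# Expression matrix and reference lists
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path, unit: str = "FPKM") -> ExpressionMatrix:
    """Read a gene-level expression TSV with a ``GeneSymbol`` column.

    Duplicate gene symbols are collapsed by the maximum per sample, which is
    conservative against false "not expressed" removals.  Non-numeric cells
    raise with the offending row and column named.
    """
    df = pd.read_csv(path, sep="\t", na_values=NA_VALUES, keep_default_na=False)
    if "GeneSymbol" not in df.columns:
        raise SchemaError(f"expression matrix {path} lacks a GeneSymbol column")
    sample_cols = [c for c in df.columns if c != "GeneSymbol"]
    for col in sample_cols:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric expression value in column {col!r}, row {row}"
            ) from exc
    collapsed = df.groupby("GeneSymbol", sort=True)[sample_cols].max()
    return ExpressionMatrix(values=collapsed, unit=unit)


def read_gene_reference(path: str | Path) -> GeneReference:
    """Read a two-column gene list TSV (Gene_Symbol, type)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"Gene_Symbol", "type"} <= set(df.columns):
        raise SchemaError(
            f"gene reference {path} needs columns Gene_Symbol and type"
        )
    ref = GeneReference()
    for symbol, label in zip(df["Gene_Symbol"], df["type"]):
        ref.labels.setdefault(symbol.strip(), set()).add(label.strip())
    return ref


def read_fusion_reference(path: str | Path,
                          rescue_path: str | Path | None = None) -> FusionReference:
    """Read a fusion list TSV (FusionName, source) and an optional rescue list.

    The rescue list is a TSV whose FusionName column (or single column) names
    fusions treated as known oncogenic for read-through rescue.
    """
    ref = FusionReference()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"FusionName", "source"} <= set(df.columns):
        raise SchemaError(f"fusion reference {path} needs FusionName and source")
    for name, source in zip(df["FusionName"], df["source"]):
        ref.tags.setdefault(name.strip(), set()).add(source.strip())
    if rescue_path is not None:
        rescue = pd.read_csv(rescue_path, sep="\t", dtype=str, keep_default_na=False)
        col = "FusionName" if "FusionName" in rescue.columns else rescue.columns[0]
        ref.rescue_names = {name.strip() for name in rescue[col] if name.strip()}
    return ref
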