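"""PFAM domain retention at fusion breakpoints.

A fusion transcript keeps, from its 5' partner (Gene1A), the gene sequence
transcriptionally UPSTREAM of the left breakpoint, and from its 3' partner
(Gene1B) the sequence transcriptionally DOWNSTREAM of the right breakpoint.
On the + strand "upstream" means lower genomic coordinates; on the - strand
the comparisons mirror.  Against each PFAM domain's genomic interval this
yields one of three statuses:

    retained  the whole domain lies in the kept region
    partial   the breakpoint falls inside the domain
    lost      the whole domain lies in the discarded region

Intervals are 1-based fully closed and a breakpoint exactly on a domain
boundary retains the boundary base.  Kinase-domain retention (any kinase
PFAM id with status retained) is surfaced per partner because fusion-directed
therapy most often targets kinases; "partial" is reported separately, never
silently promoted to retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_standardization import parse_breakpoint

logger = logging.getLogger("fusioncurate")

STATUSES = ("retained", "partial", "lost", "unknown")

#: PFAM accessions commonly used for kinase domains in these references.
DEFAULT_KINASE_PFAM_IDS = frozenset(
    {"PF00069", "PF07714", "PF01163", "PF02518", "PF03109"}
)

DOMAIN_TABLE_COLUMNS = [
    "gene_symbol",
    "transcript_id",
    "pfam_id",
    "domain_name",
    "chrom",
    "start",
    "end",
    "strand",
]


@dataclass(frozen=True)
class DomainInterval:
    """One PFAM domain occurrence in genomic coordinates (1-based, closed)."""

    gene_symbol: str
    pfam_id: str
    domain_name: str
    chrom: str
    start: int
    end: int
    strand: str
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"domain {self.pfam_id} on {self.gene_symbol}: start > end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"domain strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class DomainRetentionCall:
    sample: str
    fusion_name: str
    partner: str  # "Gene1A" or "Gene1B"
    gene_symbol: str
    transcript_id: str | None
    pfam_id: str
    domain_name: str
    status: str


class DomainIndex:
    """Domain intervals grouped by gene, with interval trees for point queries."""

    def __init__(self) -> None:
        self._by_gene: dict[str, list[DomainInterval]] = {}
        self._trees: dict[str, IntervalTree] = {}

    def add(self, interval: DomainInterval) -> None:
        bucket = self._by_gene.setdefault(interval.gene_symbol, [])
        if interval in bucket:  # duplicate rows collapse
            return
        bucket.append(interval)
        tree = self._trees.setdefault(interval.gene_symbol, IntervalTree())
        # closed genomic interval -> half-open tree interval
        tree.addi(interval.start, interval.end + 1, interval)

    def domains(self, gene_symbol: str) -> list[DomainInterval]:
        return list(self._by_gene.get(gene_symbol, []))

    def overlapping(self, gene_symbol: str, pos: int) -> list[DomainInterval]:
        tree = self._trees.get(gene_symbol)
        if tree is None:
            return []
        return [hit.data for hit in tree.at(pos)]

    def genes(self) -> list[str]:
        return sorted(self._by_gene)


def build_domain_index(table: Iterable[DomainInterval]) -> DomainIndex:
    """Index validated domain intervals by gene; malformed rows are dropped with a log."""
    index = DomainIndex()
    for interval in table:
        index.add(interval)
    return index


def read_domain_table(path) -> DomainIndex:
    """Read the domain-location TSV (gene, transcript, pfam id/name, interval, strand)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in DOMAIN_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"domain table {path} missing column(s): {missing}")
    index = DomainIndex()
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            interval = DomainInterval(
                gene_symbol=row.gene_symbol,
                transcript_id=row.transcript_id or None,
                pfam_id=row.pfam_id,
                domain_name=row.domain_name,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
            )
        except ValueError as exc:
            n_rejected += 1
            logger.warning("rejected domain row (%s)", exc)
            continue
        index.add(interval)
    if n_rejected:
        logger.warning("domain table: %d malformed row(s) rejected", n_rejected)
    return index


# ---------------------------------------------------------------------------
# Retention semantics
# ---------------------------------------------------------------------------


def retention_status(partner: str, strand: str, start: int, end: int,
                     breakpoint_pos: int) -> str:
    """Status of one closed domain interval against one breakpoint.

    ``partner`` is "Gene1A" (5', keeps transcriptionally upstream of the
    breakpoint, breakpoint base included) or "Gene1B" (3', keeps downstream,
    breakpoint base included).
    """
    bp = breakpoint_pos
    keeps_low = (partner == "Gene1A") == (strand == "+")
    # keeps_low: the retained region is {pos <= bp}; else it is {pos >= bp}
    if keeps_low:
        if end <= bp:
            return "retained"
        if start <= bp:
            return "partial"
        return "lost"
    if start >= bp:
        return "retained"
    if end >= bp:
        return "partial"
    return "lost"


def get_pfam_domain(call: pd.Series, index: DomainIndex) -> list[DomainRetentionCall]:
    """Retention status of every domain of both partners for one fusion call.

    The left breakpoint applies to Gene1A and the right to Gene1B.  A domain
    on a different chromosome than its breakpoint, or a breakpoint that cannot
    be parsed, yields status "unknown" with a log entry.
    """
    results: list[DomainRetentionCall] = []
    for partner, bp_col in (("Gene1A", "LeftBreakpoint"), ("Gene1B", "RightBreakpoint")):
        gene = call[partner]
        try:
            bp = parse_breakpoint(str(call[bp_col]))
        except (ValueError, TypeError):
            bp = None
        for domain in index.domains(gene):
            if bp is None or bp.chrom != domain.chrom:
                if bp is not None:
                    logger.warning(
                        "%s breakpoint on chr%s but domain %s of %s on chr%s; "
                        "status unknown",
                        partner, bp.chrom, domain.pfam_id, gene, domain.chrom,
                    )
                status = "unknown"
            else:
                status = retention_status(
                    partner, domain.strand, domain.start, domain.end, bp.pos
                )
            results.append(
                DomainRetentionCall(
                    sample=call["Sample"],
                    fusion_name=call["FusionName"],
                    partner=partner,
                    gene_symbol=gene,
                    transcript_id=domain.transcript_id,
                    pfam_id=domain.pfam_id,
                    domain_name=domain.domain_name,
                    status=status,
                )
            )
    return results


def domain_retention_table(calls: pd.DataFrame, index: DomainIndex) -> pd.DataFrame:
    """Long-format per-domain retention table for a cohort."""
    rows = []
    for _, call in calls.iterrows():
        for result in get_pfam_domain(call, index):
            rows.append(
                {
                    "Sample": result.sample,
                    "FusionName": result.fusion_name,
                    "partner": result.partner,
                    "gene_symbol": result.gene_symbol,
                    "transcript_id": result.transcript_id,
                    "pfam_id": result.pfam_id,
                    "domain_name": result.domain_name,
                    "status": result.status,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "Sample", "FusionName", "partner", "gene_symbol",
            "transcript_id", "pfam_id", "domain_name", "status",
        ],
    )


def kinase_domain_retained(
    calls: pd.DataFrame,
    index: DomainIndex,
    kinase_pfam_ids: Sequence[str] | frozenset[str] = DEFAULT_KINASE_PFAM_IDS,
) -> pd.DataFrame:
    """Per-call kinase-domain retention flags for both partners.

    For each partner: ``KinaseDomainRetained_*`` is true iff ANY kinase-family
    domain of that gene has status retained; ``KinaseDomainPartial_*`` flags a
    partial hit separately (partial never counts as retained).
    """
    kinase_ids = set(kinase_pfam_ids)
    flags = {
        "KinaseDomainRetained_1A": [],
        "KinaseDomainRetained_1B": [],
        "KinaseDomainPartial_1A": [],
        "KinaseDomainPartial_1B": [],
    }
    for _, call in calls.iterrows():
        statuses = {"Gene1A": set(), "Gene1B": set()}
        for result in get_pfam_domain(call, index):
            if result.pfam_id in kinase_ids:
                statuses[result.partner].add(result.status)
        flags["KinaseDomainRetained_1A"].append("retained" in statuses["Gene1A"])
        flags["KinaseDomainRetained_1B"].append("retained" in statuses["Gene1B"])
        flags["KinaseDomainPartial_1A"].append("partial" in statuses["Gene1A"])
        flags["KinaseDomainPartial_1B"].append("partial" in statuses["Gene1B"])
    return pd.DataFrame(flags, index=calls.index)


def annotate_domain_retention(
    calls: pd.DataFrame,
    index: DomainIndex,
    kinase_pfam_ids: Sequence[str] | frozenset[str] = DEFAULT_KINASE_PFAM_IDS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Append per-partner domain summaries and kinase flags to the call table.

    Returns (annotated calls, long-format per-domain table).  The summary
    columns ``DomainRetained_1A/1B`` list the retained domain names per
    partner, comma-joined.
    """
    kinase_ids = set(kinase_pfam_ids)
    long_rows = []
    summary = {
        "DomainRetained_1A": [], "DomainRetained_1B": [],
        "KinaseDomainRetained_1A": [], "KinaseDomainRetained_1B": [],
        "KinaseDomainPartial_1A": [], "KinaseDomainPartial_1B": [],
    }
    for _, call in calls.iterrows():
        results = get_pfam_domain(call, index)
        retained = {"Gene1A": set(), "Gene1B": set()}
        kinase_status = {"Gene1A": set(), "Gene1B": set()}
        for r in results:
            long_rows.append(
                {
                    "Sample": r.sample, "FusionName": r.fusion_name,
                    "partner": r.partner, "gene_symbol": r.gene_symbol,
                    "transcript_id": r.transcript_id, "pfam_id": r.pfam_id,
                    "domain_name": r.domain_name, "status": r.status,
                }
            )
            if r.status == "retained":
                retained[r.partner].add(r.domain_name)
            if r.pfam_id in kinase_ids:
                kinase_status[r.partner].add(r.status)
        summary["DomainRetained_1A"].append(",".join(sorted(retained["Gene1A"])))
        summary["DomainRetained_1B"].append(",".join(sorted(retained["Gene1B"])))
        for suffix, partner in (("1A", "Gene1A"), ("1B", "Gene1B")):
            summary[f"KinaseDomainRetained_{suffix}"].append(
                "retained" in kinase_status[partner]
            )
            summary[f"KinaseDomainPartial_{suffix}"].append(
                "partial" in kinase_status[partner]
            )
    long_table = pd.DataFrame(
        long_rows,
        columns=[
            "Sample", "FusionName", "partner", "gene_symbol",
            "transcript_id", "pfam_id", "domain_name", "status",
        ],
    )
    out = pd.concat(
        [calls.copy(), pd.DataFrame(summary, index=calls.index)], axis=1
    )
    return out, long_table
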