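"""QC filtering of standardized fusion calls.

Four per-record stages, applied in order, each with a recorded decision:

1. artifact filtering — drop calls whose FusionAnnotator tokens match the
   red-flag alternation (fusions recurrent in normal tissue, gene homologs);
2. read-through filtering — drop transcriptional read-throughs unless the
   fusion is a known oncogenic event (Mitelman-style rescue);
3. read-support filtering — drop calls with no junction reads or with
   disproportionate spanning support (spanningDelta >= cutoff);
4. expression filtering — drop calls where both partners are not expressed.

Every input record receives exactly one decision per stage it reaches; the
full ledger is the provenance trail for the retained set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .io_standardization import (
    ExpressionMatrix,
    FusionReference,
    parse_annots,
)

#: Red-flag alternation over annotation tokens.  Matching is substring-per-token,
#: so the "Normal" alternative hits both Greger_Normal and Babiceanu_Normal.
DEFAULT_ARTIFACT_FILTER = "GTEx_recurrent_STARF2019|DGD_PARALOGS|Normal|BodyMap"

_READTHROUGH = re.compile(r"READTHRU|read-through|readthrough", re.IGNORECASE)

QC_STAGES = ("artifact", "readthrough", "read_support", "expression")

REASONS = (
    "ARTIFACT_DB",
    "READTHROUGH",
    "READTHROUGH_RESCUED",
    "NO_JUNCTION_READS",
    "SPANNING_DELTA",
    "NOT_EXPRESSED",
    "PASS",
)

LEDGER_COLUMNS = [
    "record_id",
    "Sample",
    "FusionName",
    "Caller",
    "stage",
    "retained",
    "reason",
    "matched_token",
]


@dataclass
class FilterParams:
    """Tunable thresholds of the QC cascade.

    artifact_filter      '|'-separated alternation matched per annotation token
    readthrough_filter   whether the read-through stage is active
    junction_min         minimum junction reads (remove when count < this)
    spanning_delta_max   remove when SpanningFragCount - JunctionReadCount >= this
    expression_min       both partners below this (FPKM/TPM) -> not expressed
    """

    artifact_filter: str = DEFAULT_ARTIFACT_FILTER
    readthrough_filter: bool = True
    junction_min: int = 1
    spanning_delta_max: int = 100
    expression_min: float = 1.0
    expression_unit: str = "FPKM"

    def __post_init__(self) -> None:
        if self.junction_min < 0:
            raise ValueError("junction_min must be >= 0")
        if self.spanning_delta_max <= 0:
            raise ValueError("spanning_delta_max must be > 0")
        if self.expression_min < 0:
            raise ValueError("expression_min must be >= 0")

    def artifact_alternatives(self) -> list[str]:
        alts = [alt.strip() for alt in self.artifact_filter.split("|") if alt.strip()]
        for alt in alts:
            try:
                re.compile(alt)
            except re.error as exc:
                raise ValueError(
                    f"invalid artifact_filter alternative {alt!r}: {exc}"
                ) from exc
        return alts


@dataclass
class StageResult:
    retained: pd.DataFrame
    decisions: pd.DataFrame  # LEDGER_COLUMNS


def _decision_rows(df: pd.DataFrame, stage: str, retained: pd.Series,
                   reason: pd.Series, matched: pd.Series) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "record_id": df.index,
            "Sample": df["Sample"].to_numpy(),
            "FusionName": df["FusionName"].to_numpy(),
            "Caller": df["Caller"].to_numpy(),
            "stage": stage,
            "retained": retained.to_numpy(),
            "reason": reason.to_numpy(),
            "matched_token": matched.to_numpy(),
        },
        columns=LEDGER_COLUMNS,
    )


def _token_sets(df: pd.DataFrame) -> pd.Series:
    return df["annots"].map(parse_annots)


# ---------------------------------------------------------------------------
# Stage 1: artifact databases
# ---------------------------------------------------------------------------


def filter_artifacts(calls: pd.DataFrame, params: FilterParams) -> StageResult:
    """Remove calls whose annotation tokens match the red-flag alternation.

    A call is removed iff ANY of its tokens contains ANY alternative as a
    regex match (substring semantics).  With the default alternation the
    Greger_Normal and Babiceanu_Normal tokens are removed via "Normal" while
    HGNC_GENEFAM and ConjoinG are retained.
    """
    patterns = [re.compile(alt) for alt in params.artifact_alternatives()]

    def first_hit(tokens: frozenset[str]) -> str | None:
        for tok in sorted(tokens):
            for pat in patterns:
                if pat.search(tok):
                    return tok
        return None

    hits = _token_sets(calls).map(first_hit)
    removed = hits.notna()
    reason = removed.map({True: "ARTIFACT_DB", False: "PASS"})
    decisions = _decision_rows(calls, "artifact", ~removed, reason, hits)
    return StageResult(retained=calls.loc[~removed], decisions=decisions)


# ---------------------------------------------------------------------------
# Stage 2: read-throughs with oncogenic rescue
# ---------------------------------------------------------------------------


def filter_readthroughs(calls: pd.DataFrame, rescue: FusionReference | None,
                        enabled: bool = True) -> StageResult:
    """Remove read-through calls unless rescued as known oncogenic.

    A call is a read-through when any annotation token contains READTHRU /
    read-through / readthrough (case-insensitive).  It is rescued — retained
    with reason READTHROUGH_RESCUED — when a Mitelman token is present or the
    fusion name is in the rescue list.  With ``enabled=False`` every call is
    retained.
    """
    tokens = _token_sets(calls)
    if not enabled:
        reason = pd.Series("PASS", index=calls.index)
        matched = pd.Series([None] * len(calls), index=calls.index, dtype=object)
        decisions = _decision_rows(
            calls, "readthrough", pd.Series(True, index=calls.index), reason, matched
        )
        return StageResult(retained=calls, decisions=decisions)

    rescue_names = rescue.rescue_names if rescue is not None else set()

    def rt_token(toks: frozenset[str]) -> str | None:
        for tok in sorted(toks):
            if _READTHROUGH.search(tok):
                return tok
        return None

    rt_hits = tokens.map(rt_token)
    is_rt = rt_hits.notna()
    has_mitelman = tokens.map(lambda t: any("Mitelman" in tok for tok in t))
    in_rescue_list = calls["FusionName"].isin(rescue_names)
    rescued = is_rt & (has_mitelman | in_rescue_list)
    removed = is_rt & ~rescued

    reason = pd.Series("PASS", index=calls.index)
    reason[rescued] = "READTHROUGH_RESCUED"
    reason[removed] = "READTHROUGH"
    decisions = _decision_rows(calls, "readthrough", ~removed, reason, rt_hits)
    return StageResult(retained=calls.loc[~removed], decisions=decisions)


# ---------------------------------------------------------------------------
# Stage 3: read support
# ---------------------------------------------------------------------------


def filter_read_support(calls: pd.DataFrame, params: FilterParams) -> StageResult:
    """Remove calls with too few junction reads or excessive spanning delta.

    Removal conditions: JunctionReadCount < junction_min, or
    SpanningFragCount - JunctionReadCount >= spanning_delta_max.  When both
    hold the reason field records NO_JUNCTION_READS and matched_token lists
    both conditions.
    """
    junction = calls["JunctionReadCount"]
    delta = calls["SpanningFragCount"] - junction
    low_junction = junction < params.junction_min
    high_delta = delta >= params.spanning_delta_max
    removed = low_junction | high_delta

    reason = pd.Series("PASS", index=calls.index)
    reason[high_delta] = "SPANNING_DELTA"
    reason[low_junction] = "NO_JUNCTION_READS"  # first-listed reason wins

    def describe(i: int) -> str | None:
        parts = []
        if low_junction.at[i]:
            parts.append(f"junction={junction.at[i]}")
        if high_delta.at[i]:
            parts.append(f"delta={delta.at[i]}")
        return ";".join(parts) or None

    matched = pd.Series([describe(i) for i in calls.index], index=calls.index,
                        dtype=object)
    decisions = _decision_rows(calls, "read_support", ~removed, reason, matched)
    return StageResult(retained=calls.loc[~removed], decisions=decisions)


# ---------------------------------------------------------------------------
# Stage 4: expression
# ---------------------------------------------------------------------------


def expression_filter_fusion(calls: pd.DataFrame, expr: ExpressionMatrix,
                             params: FilterParams) -> StageResult:
    """Remove calls where BOTH partner genes are not expressed in the sample.

    A gene is not expressed when its value is below ``expression_min`` or the
    gene is absent from the matrix (absence treated as zero expression).
    Secondary partners (Gene2A/Gene2B) are not consulted.  A sample missing
    from the matrix is an error naming the sample.
    """
    missing_samples = sorted(set(calls["Sample"]) - set(expr.samples))
    if missing_samples:
        raise KeyError(
            "sample(s) absent from expression matrix: " + ", ".join(missing_samples)
        )

    def low(gene: str, sample: str) -> bool:
        value = expr.get(gene, sample)
        return value is None or value < params.expression_min

    removed_flags = []
    matched_vals: list[str | None] = []
    for i in calls.index:
        sample = calls.at[i, "Sample"]
        gene_a, gene_b = calls.at[i, "Gene1A"], calls.at[i, "Gene1B"]
        both_low = low(gene_a, sample) and low(gene_b, sample)
        removed_flags.append(both_low)
        if both_low:
            va, vb = expr.get(gene_a, sample), expr.get(gene_b, sample)
            matched_vals.append(f"{gene_a}={va};{gene_b}={vb}")
        else:
            matched_vals.append(None)
    removed = pd.Series(removed_flags, index=calls.index)
    reason = removed.map({True: "NOT_EXPRESSED", False: "PASS"})
    matched = pd.Series(matched_vals, index=calls.index, dtype=object)
    decisions = _decision_rows(calls, "expression", ~removed, reason, matched)
    return StageResult(retained=calls.loc[~removed], decisions=decisions)


# ---------------------------------------------------------------------------
# Composite cascade
# ---------------------------------------------------------------------------


def fusion_filtering_QC(
    calls: pd.DataFrame,
    expr: ExpressionMatrix | None = None,
    params: FilterParams | None = None,
    rescue: FusionReference | None = None,
    stage_order: Sequence[str] = QC_STAGES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the QC cascade; returns (retained calls, full decision ledger).

    Stages run in ``stage_order`` (default: artifact, readthrough,
    read_support, expression); a record removed at one stage is not
    re-examined later, so the ledger covers every input record exactly up to
    its removal stage.  Because each stage predicate is per-record and
    independent, the final retained set does not depend on the order.
    The expression stage is skipped when no matrix is supplied.
    """
    params = params or FilterParams()
    unknown = set(stage_order) - set(QC_STAGES)
    if unknown:
        raise ValueError(f"unknown QC stage(s): {sorted(unknown)}")

    current = calls
    ledgers = []
    for stage in stage_order:
        if stage == "artifact":
            result = filter_artifacts(current, params)
        elif stage == "readthrough":
            result = filter_readthroughs(current, rescue, params.readthrough_filter)
        elif stage == "read_support":
            result = filter_read_support(current, params)
        else:  # expression
            if expr is None:
                continue
            result = expression_filter_fusion(current, expr, params)
        ledgers.append(result.decisions)
        current = result.retained
    ledger = (
        pd.concat(ledgers, ignore_index=True)
        if ledgers
        else pd.DataFrame(columns=LEDGER_COLUMNS)
    )
    return current, ledger


def final_reason(ledger: pd.DataFrame) -> pd.Series:
    """Per-record terminal QC fate: removal reason, rescue, or PASS.

    Index = record_id.  A record's fate is the reason of its removal stage if
    it was removed, READTHROUGH_RESCUED if it was rescued and never removed,
    otherwise PASS.
    """
    fates = {}
    for record_id, group in ledger.groupby("record_id", sort=False):
        removal = group.loc[~group["retained"]]
        if len(removal):
            fates[record_id] = removal.iloc[0]["reason"]
        elif (group["reason"] == "READTHROUGH_RESCUED").any():
            fates[record_id] = "READTHROUGH_RESCUED"
        else:
            fates[record_id] = "PASS"
    return pd.Series(fates, name="reason")
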