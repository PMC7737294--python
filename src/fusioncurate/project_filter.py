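"""Cohort-level prioritization of QC-passed, annotated fusion calls.

Two branches feed the final putative oncogenic set:

* the DRIVER branch keeps calls in which a partner carries a cancer gene-list
  label (oncogene, tumor suppressor, kinase, transcription factor, COSMIC) or
  the fusion name is in a known-fusion reference (e.g. TCGA), then removes
  fusion names seen across too many groups (> 4 broad histologies by default,
  a pattern typical of artifacts and pseudogene fusions);

* the SCAVENGE branch recovers, from the NON-driver remainder, novel fusions
  with credible support: called by at least two algorithms, in-frame or
  frameshift, not a local rearrangement/inversion artifact, recurrent
  (>= 2 samples) within exactly one group, and without promiscuous partners
  (a gene fused to >= 5 distinct partners in one sample is discarded).

The two branches are disjoint by construction; their union, tagged by origin,
is the prioritized output table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation import has_driver_annotation
from .io_standardization import parse_annots

LOCAL_ARTIFACT_TOKENS = ("LOCAL_REARRANGEMENT", "LOCAL_INVERSION")


@dataclass
class CohortConfig:
    """Thresholds of project-specific filtering.

    min_callers                    distinct algorithms required to scavenge
    min_samples_per_group          recurrence floor within a group
    max_groups_for_scavenged       scavenged fusions must stay within this many groups
    max_partners                   a gene fused to >= this many distinct partners
                                   in one sample is treated as promiscuous
    max_group_prevalence_for_drivers  driver fusions in MORE than this many
                                   groups are removed
    """

    sample_column: str = "Sample"
    group_column: str = "group"
    min_callers: int = 2
    min_samples_per_group: int = 2
    max_groups_for_scavenged: int = 1
    max_partners: int = 5
    max_group_prevalence_for_drivers: int = 4

    def __post_init__(self) -> None:
        for name in (
            "min_callers", "min_samples_per_group", "max_groups_for_scavenged",
            "max_partners", "max_group_prevalence_for_drivers",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def attach_groups(cohort: pd.DataFrame, metadata: pd.DataFrame,
                  config: CohortConfig) -> pd.DataFrame:
    """Join the sample-metadata group column onto the cohort table."""
    meta = metadata[[config.sample_column, config.group_column]].drop_duplicates()
    merged = cohort.merge(meta, on=config.sample_column, how="left")
    merged.index = cohort.index
    missing = merged[config.group_column].isna()
    if missing.any():
        samples = sorted(set(merged.loc[missing, config.sample_column]))
        raise KeyError(f"samples missing from metadata: {samples}")
    return merged


def called_by_n_callers(cohort: pd.DataFrame,
                        config: CohortConfig | None = None) -> pd.DataFrame:
    """Append caller_count = number of distinct callers per (sample, fusion)."""
    config = config or CohortConfig()
    if cohort.empty:
        out = cohort.copy()
        out["caller_count"] = pd.Series(dtype="int64")
        return out
    counts = (
        cohort.groupby([config.sample_column, "FusionName"])["Caller"]
        .nunique()
        .rename("caller_count")
    )
    out = cohort.merge(
        counts, left_on=[config.sample_column, "FusionName"], right_index=True
    )
    out.index = cohort.index
    return out


def fusion_driver(cohort: pd.DataFrame) -> pd.DataFrame:
    """Subset of calls with a driver-labeled partner or known-fusion tag."""
    if cohort.empty:
        return cohort.copy()
    mask = cohort.apply(has_driver_annotation, axis=1)
    return cohort.loc[mask]


def _group_prevalence(cohort: pd.DataFrame, config: CohortConfig) -> pd.Series:
    """Distinct group count per fusion name, over the whole (post-QC) cohort."""
    return cohort.groupby("FusionName")[config.group_column].nunique()


def _multifused_genes(cohort: pd.DataFrame, config: CohortConfig) -> set[tuple[str, str]]:
    """(sample, gene) pairs where the gene has >= max_partners distinct partners."""
    pairs: dict[tuple[str, str], set[str]] = {}
    for sample, a, b in zip(
        cohort[config.sample_column], cohort["Gene1A"], cohort["Gene1B"]
    ):
        pairs.setdefault((sample, a), set()).add(b)
        pairs.setdefault((sample, b), set()).add(a)
    return {
        key for key, partners in pairs.items()
        if len(partners) >= config.max_partners
    }


def scavenge_recurrent(cohort: pd.DataFrame, driver_index: pd.Index,
                       config: CohortConfig) -> pd.DataFrame:
    """Recover novel recurrent fusions from the non-driver remainder.

    Keeps non-driver records with: caller_count >= min_callers; fusion type
    in-frame or frameshift; no LOCAL_INVERSION / LOCAL_REARRANGEMENT token;
    recurrence >= min_samples_per_group within some group; present in at most
    max_groups_for_scavenged groups; and neither partner promiscuously fused
    (>= max_partners distinct partners in the same sample, measured over the
    whole post-QC cohort).
    """
    candidates = cohort.drop(index=driver_index, errors="ignore")
    if candidates.empty:
        return candidates

    with_counts = called_by_n_callers(cohort, config)
    caller_ok = with_counts.loc[candidates.index, "caller_count"] >= config.min_callers
    frame_ok = candidates["Fusion_Type"].isin(["in-frame", "frameshift"])
    tokens = candidates["annots"].map(parse_annots)
    clean = tokens.map(
        lambda toks: not any(
            artifact in tok for tok in toks for artifact in LOCAL_ARTIFACT_TOKENS
        )
    )

    # recurrence: distinct samples per (fusion, group)
    per_group = cohort.groupby(["FusionName", config.group_column])[
        config.sample_column
    ].nunique()
    recurrent_names = {
        name for (name, _), n in per_group.items()
        if n >= config.min_samples_per_group
    }
    recurrent = candidates["FusionName"].isin(recurrent_names)

    prevalence = _group_prevalence(cohort, config)
    few_groups = candidates["FusionName"].map(prevalence) <= config.max_groups_for_scavenged

    multifused = _multifused_genes(cohort, config)
    not_promiscuous = pd.Series(
        [
            (s, a) not in multifused and (s, b) not in multifused
            for s, a, b in zip(
                candidates[config.sample_column],
                candidates["Gene1A"],
                candidates["Gene1B"],
            )
        ],
        index=candidates.index,
    )

    keep = caller_ok & frame_ok & clean & recurrent & few_groups & not_promiscuous
    return candidates.loc[keep]


def prevalence_filter_drivers(drivers: pd.DataFrame, cohort: pd.DataFrame,
                              config: CohortConfig) -> pd.DataFrame:
    """Drop driver fusions observed in more than the allowed number of groups."""
    if drivers.empty:
        return drivers
    prevalence = _group_prevalence(cohort, config)
    keep = drivers["FusionName"].map(prevalence) <= config.max_group_prevalence_for_drivers
    return drivers.loc[keep]


DEDUP_KEY = ["Sample", "FusionName", "Caller", "LeftBreakpoint", "RightBreakpoint"]


def putative_oncogenic_set(drivers: pd.DataFrame,
                           scavenged: pd.DataFrame) -> pd.DataFrame:
    """Union of the two branches, origin-tagged, deduplicated on the record key.

    The branches are disjoint by construction (scavenging starts from
    non-driver records); a record somehow present in both keeps origin
    "driver".
    """
    overlap = drivers.index.intersection(scavenged.index)
    if len(overlap):
        scavenged = scavenged.drop(index=overlap)
    drivers = drivers.copy()
    drivers["origin"] = "driver"
    scavenged = scavenged.copy()
    scavenged["origin"] = "scavenged"
    merged = pd.concat([drivers, scavenged])
    merged = merged.drop_duplicates(subset=DEDUP_KEY, keep="first")
    return merged.sort_values(
        ["Sample", "FusionName", "Caller"], kind="stable"
    )


def prioritize(cohort: pd.DataFrame, metadata: pd.DataFrame,
               config: CohortConfig | None = None) -> pd.DataFrame:
    """Full project-specific filtering on an annotated, QC-passed cohort.

    ``cohort`` must carry the annotation columns (Gene1A_anno, Gene1B_anno,
    Fusion_anno); ``metadata`` maps samples to groups.  Returns the putative
    oncogenic set with an ``origin`` column.
    """
    config = config or CohortConfig()
    grouped = attach_groups(cohort, metadata, config)
    drivers = fusion_driver(grouped)
    drivers = prevalence_filter_drivers(drivers, grouped, config)
    scavenged = scavenge_recurrent(grouped, fusion_driver(grouped).index, config)
    assert len(drivers.index.intersection(scavenged.index)) == 0
    return putative_oncogenic_set(drivers, scavenged)
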