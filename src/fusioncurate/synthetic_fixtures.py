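"""Deterministic synthetic fusion cohorts with planted ground truth.

The generator emulates the caller-output entry point of the pipeline: it
writes STAR-Fusion and Arriba dialect TSVs per sample, an expression matrix,
gene/fusion/rescue/domain/exon reference tables and sample metadata, plus a
manifest recording the planted class and expected pipeline fate of every
record.  No read-level simulation happens — records start life at the
caller-output level.

Each planted class violates exactly one filtering rule (or none), so the QC
ledger and prioritization branches can be checked record-for-record:

=======================  =====================================================
class                    expected fate
=======================  =====================================================
driver                   QC pass, driver branch, in final set
rescuable_readthrough    read-through rescued (Mitelman), driver, in final set
plain_readthrough        removed: READTHROUGH
artifact_db_hit          removed: ARTIFACT_DB
zero_junction            removed: NO_JUNCTION_READS
high_spanning_delta      removed: SPANNING_DELTA
not_expressed            removed: NOT_EXPRESSED
local_rearrangement      QC pass, excluded from scavenge (LOCAL_* token)
multifused               QC pass, excluded from scavenge (promiscuous gene)
cross_group_ubiquitous   QC pass, excluded from scavenge (> 1 group)
scavengeable_recurrent   QC pass, scavenged branch, in final set
ubiquitous_driver        QC pass, driver branch, prevalence-removed (> 4 groups)
=======================  =====================================================

Gene symbols and coordinates are synthetic (GENEnnnn / ONCGnnnn on ordinary
chromosome names with invented positions), except a small named cast
(KIAA1549--BRAF, P2RY8--CRLF2, EWSR1--FLI1, C11orf95--RELA, MYB--QKI) used in
documentation examples; those coordinates are synthetic too.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

STARFUSION_HEADER = [
    "#FusionName", "JunctionReadCount", "SpanningFragCount",
    "LeftBreakpoint", "RightBreakpoint", "PROT_FUSION_TYPE", "annots",
]

ARRIBA_HEADER = [
    "#gene1", "gene2", "strand1(gene/fusion)", "strand2(gene/fusion)",
    "breakpoint1", "breakpoint2", "split_reads1", "split_reads2",
    "discordant_mates", "reading_frame", "confidence", "annots",
]

PLANTED_CLASSES = (
    "driver",
    "rescuable_readthrough",
    "plain_readthrough",
    "artifact_db_hit",
    "zero_junction",
    "high_spanning_delta",
    "not_expressed",
    "local_rearrangement",
    "multifused",
    "cross_group_ubiquitous",
    "scavengeable_recurrent",
    "ubiquitous_driver",
)

ARTIFACT_TOKENS = (
    "GTEx_recurrent_STARF2019",
    "DGD_PARALOGS",
    "Greger_Normal",
    "Babiceanu_Normal",
    "BodyMap",
)

#: Named cast with curated labels; coordinates remain synthetic.
NAMED_CAST_LABELS = {
    "BRAF": ["oncogene", "kinase:Pkinase_Tyr", "cosmic", "biotype:protein_coding"],
    "KIAA1549": ["biotype:protein_coding"],
    "FLI1": ["tf_curated", "cosmic", "biotype:protein_coding"],
    "EWSR1": ["cosmic", "biotype:protein_coding"],
    "RELA": ["tf_curated", "biotype:protein_coding"],
    "C11orf95": ["biotype:protein_coding"],
    "MYB": ["oncogene", "tf_curated", "biotype:protein_coding"],
    "QKI": ["tsg", "biotype:protein_coding"],
    "CRLF2": ["oncogene", "biotype:protein_coding"],
    "P2RY8": ["biotype:protein_coding"],
    # pediatric additions
    "MYBL1": ["oncogene"],
    "SNCAIP": ["oncogene"],
    "FOXR2": ["oncogene"],
    "TTYH1": ["oncogene"],
    "TERT": ["oncogene"],
    "BCOR": ["tsg"],
}

NAMED_FUSIONS = [
    ("KIAA1549", "BRAF"),
    ("EWSR1", "FLI1"),
    ("C11orf95", "RELA"),
    ("MYB", "QKI"),
]

KINASE_PFAM = "PF00069"


@dataclass
class CohortRecipe:
    """Study conditions for one synthetic cohort.

    Event counts are fusion EVENTS; the row count each contributes depends on
    how many samples and callers observe it (documented per class below), and
    is sized so every class yields on the order of 50 records under the
    defaults: 10 groups of 10 samples.
    """

    seed: int = 42
    n_groups: int = 10
    samples_per_group: int = 10
    n_drivers: int = 25                 # x1 sample x2 callers = 50 rows
    n_tcga_route_drivers: int = 5       # of n_drivers, via fusion-list tag only
    n_rescuable_readthroughs: int = 25  # x1 sample x2 callers = 50 rows
    n_plain_readthroughs: int = 50      # x1 sample x1 caller = 50 rows
    n_artifact_hits: int = 50           # x1 x1 = 50 rows
    n_zero_junction: int = 50           # x1 x1 = 50 rows
    n_high_delta: int = 50              # x1 x1 = 50 rows
    n_not_expressed: int = 50           # x1 x1 = 50 rows
    n_local_rearrangements: int = 12    # x2 samples x2 callers = 48 rows
    n_multifused_sets: int = 2          # x5 partners x2 samples x2 callers = 40 rows
    n_cross_group: int = 6              # x4 samples x2 callers = 48 rows
    n_scavengeable: int = 12            # x2 samples x2 callers = 48 rows
    n_ubiquitous_drivers: int = 5       # x5 groups x2 callers = 50 rows

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name != "seed" and value < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_tcga_route_drivers > self.n_drivers:
            raise ValueError("n_tcga_route_drivers cannot exceed n_drivers")


@dataclass
class _State:
    rng: np.random.Generator
    samples: list[str]
    group_of: dict[str, str]
    loci: dict[str, tuple[str, int, str]] = field(default_factory=dict)  # chrom,start,strand
    gene_labels: dict[str, list[str]] = field(default_factory=dict)
    fusion_tags: dict[str, str] = field(default_factory=dict)
    rescue_names: list[str] = field(default_factory=list)
    expressed_genes: set[str] = field(default_factory=set)
    silent_genes: set[str] = field(default_factory=set)
    caller_rows: dict[tuple[str, str], list[list[str]]] = field(default_factory=dict)
    manifest_records: list[dict] = field(default_factory=list)
    gene_counter: int = 0
    onco_counter: int = 0
    locus_counter: int = 0

    def new_gene(self, oncogenic: bool = False) -> str:
        if oncogenic:
            self.onco_counter += 1
            gene = f"ONCG{self.onco_counter:04d}"
            self.gene_labels[gene] = ["oncogene", "kinase:Pkinase",
                                      "biotype:protein_coding"]
        else:
            self.gene_counter += 1
            gene = f"GENE{self.gene_counter:04d}"
        self.allocate_locus(gene)
        return gene

    def allocate_locus(self, gene: str, chrom: str | None = None) -> None:
        if gene in self.loci:
            return
        i = self.locus_counter
        self.locus_counter += 1
        chrom = chrom or str((i % 22) + 1)
        start = 1_000_000 + (i // 22) * 200_000
        strand = "+" if i % 2 == 0 else "-"
        self.loci[gene] = (chrom, start, strand)


def _key(sample: str, fusion: str, caller: str, left: str, right: str) -> str:
    return "|".join([sample, fusion, caller, left, right])


def _breakpoints(state: _State, gene_a: str, gene_b: str) -> tuple[str, str, str, str]:
    """Left/right breakpoints ("chrom:pos") and strands for a gene pair.

    The 3' breakpoint is placed upstream (transcriptionally) of the gene body
    midpoint so that domains in the distal half are retained in the fusion.
    """
    chrom_a, start_a, strand_a = state.loci[gene_a]
    chrom_b, start_b, strand_b = state.loci[gene_b]
    pos_a = start_a + 25_000  # mid-gene
    pos_b = start_b + (5_000 if strand_b == "+" else 45_000)
    return (
        f"{chrom_a}:{pos_a}", f"{chrom_b}:{pos_b}", strand_a, strand_b,
    )


def _read_counts(state: _State, mode: str) -> tuple[int, int]:
    rng = state.rng
    if mode == "zero_junction":
        return 0, int(rng.integers(1, 20))
    if mode == "high_delta":
        junction = int(rng.integers(1, 6))
        return junction, junction + int(rng.integers(100, 200))
    junction = int(rng.integers(5, 60))
    return junction, junction + int(rng.integers(0, 50))


_CONFIDENCE = ("high", "medium", "low")


def _plant(
    state: _State,
    gene_a: str,
    gene_b: str,
    samples: list[str],
    callers: tuple[str, ...],
    annots: tuple[str, ...],
    frame: str,
    read_mode: str,
    planted_class: str,
    qc_reason: str,
    in_final: bool,
    origin: str | None,
) -> None:
    fusion = f"{gene_a}--{gene_b}"
    left, right, strand_a, strand_b = _breakpoints(state, gene_a, gene_b)
    annot_cell = (
        "[" + ",".join(f'"{tok}"' for tok in annots) + "]" if annots else ""
    )
    for sample in samples:
        for caller in callers:
            junction, spanning = _read_counts(state, read_mode)
            if caller == "STARFUSION":
                prot = {"in-frame": "INFRAME", "frameshift": "FRAMESHIFT"}.get(
                    frame, "."
                )
                row = [
                    fusion, str(junction), str(spanning),
                    f"chr{left}:{strand_a}", f"chr{right}:{strand_b}",
                    prot, annot_cell,
                ]
                state.caller_rows.setdefault((sample, "STARFUSION"), []).append(row)
            else:
                reading = {"in-frame": "in-frame", "frameshift": "out-of-frame"}.get(
                    frame, "."
                )
                split1 = junction // 2
                row = [
                    gene_a, gene_b,
                    f"{strand_a}/{strand_a}", f"{strand_b}/{strand_b}",
                    left, right,
                    str(split1), str(junction - split1), str(spanning),
                    reading,
                    _CONFIDENCE[int(state.rng.integers(0, 3))],
                    annot_cell,
                ]
                state.caller_rows.setdefault((sample, "ARRIBA"), []).append(row)
            state.manifest_records.append(
                {
                    "key": _key(sample, fusion, caller, left, right),
                    "sample": sample,
                    "fusion_name": fusion,
                    "caller": caller,
                    "left_breakpoint": left,
                    "right_breakpoint": right,
                    "class": planted_class,
                    "qc_reason": qc_reason,
                    "in_final": in_final,
                    "origin": origin,
                }
            )


def _pick_samples(state: _State, n: int, group: str | None = None) -> list[str]:
    pool = (
        [s for s in state.samples if state.group_of[s] == group]
        if group
        else state.samples
    )
    idx = state.rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def _pick_group(state: _State) -> str:
    groups = sorted(set(state.group_of.values()))
    return groups[int(state.rng.integers(0, len(groups)))]


# ---------------------------------------------------------------------------
# Cohort construction
# ---------------------------------------------------------------------------


def generate_cohort(recipe: CohortRecipe, out_dir: str | Path) -> dict:
    """Write a full synthetic cohort to ``out_dir`` and return its manifest.

    Outputs: ``<sample>.starfusion.tsv`` / ``<sample>.arriba.tsv`` per sample,
    ``expression.tsv``, ``genelistreference.tsv``, ``fusionreference.tsv``,
    ``rescue_list.tsv``, ``domains.tsv``, ``pfam_description.tsv``,
    ``exons.tsv``, ``metadata.tsv`` and ``manifest.json``.  Identical
    recipe+seed produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(recipe.seed)

    samples, group_of = [], {}
    for g in range(recipe.n_groups):
        group = f"GRP{g + 1:02d}"
        for k in range(recipe.samples_per_group):
            sample = f"S{g * recipe.samples_per_group + k + 1:03d}"
            samples.append(sample)
            group_of[sample] = group
    state = _State(rng=rng, samples=samples, group_of=group_of)

    for gene, labels in NAMED_CAST_LABELS.items():
        state.gene_labels[gene] = list(labels)
        state.allocate_locus(gene)
    for gene_a, gene_b in NAMED_FUSIONS + [("P2RY8", "CRLF2")]:
        state.fusion_tags.setdefault(f"{gene_a}--{gene_b}", "TCGA")

    _plant_drivers(state, recipe)
    _plant_rescuable(state, recipe)
    _plant_simple_qc_classes(state, recipe)
    _plant_local_rearrangements(state, recipe)
    _plant_multifused(state, recipe)
    _plant_cross_group(state, recipe)
    _plant_scavengeable(state, recipe)
    _plant_ubiquitous_drivers(state, recipe)

    _write_caller_files(state, out)
    _write_expression(state, out)
    _write_references(state, out)
    _write_metadata(state, out)

    manifest = {
        "recipe": asdict(recipe),
        "records": sorted(state.manifest_records, key=lambda r: r["key"]),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest


def _plant_drivers(state: _State, recipe: CohortRecipe) -> None:
    named = list(NAMED_FUSIONS)
    for i in range(recipe.n_drivers):
        tcga_route = i < recipe.n_tcga_route_drivers
        if tcga_route:
            # unannotated partners; driver status comes from the fusion list
            gene_a, gene_b = state.new_gene(), state.new_gene()
            state.fusion_tags[f"{gene_a}--{gene_b}"] = "TCGA"
        elif named:
            gene_a, gene_b = named.pop(0)
        else:
            gene_a, gene_b = state.new_gene(), state.new_gene(oncogenic=True)
        state.expressed_genes.update([gene_a, gene_b])
        _plant(
            state, gene_a, gene_b, _pick_samples(state, 1),
            ("STARFUSION", "ARRIBA"), ("INTRACHROMOSOMAL",), "in-frame", "ok",
            "driver", "PASS", True, "driver",
        )


def _plant_rescuable(state: _State, recipe: CohortRecipe) -> None:
    for i in range(recipe.n_rescuable_readthroughs):
        if i == 0:
            gene_a, gene_b = "P2RY8", "CRLF2"
        else:
            gene_a, gene_b = state.new_gene(), state.new_gene(oncogenic=True)
        state.expressed_genes.update([gene_a, gene_b])
        # exercise both rescue routes: annotation token vs rescue-list lookup
        if i % 2 == 0:
            annots = ("READTHRU", "Mitelman")
        else:
            annots = ("READTHRU",)
            state.rescue_names.append(f"{gene_a}--{gene_b}")
        _plant(
            state, gene_a, gene_b, _pick_samples(state, 1),
            ("STARFUSION", "ARRIBA"), annots, "in-frame", "ok",
            "rescuable_readthrough", "READTHROUGH_RESCUED", True, "driver",
        )


def _plant_simple_qc_classes(state: _State, recipe: CohortRecipe) -> None:
    specs = [
        (recipe.n_plain_readthroughs, "plain_readthrough", ("READTHRU",),
         "ok", "READTHROUGH", False),
        (recipe.n_artifact_hits, "artifact_db_hit", None, "ok",
         "ARTIFACT_DB", False),
        (recipe.n_zero_junction, "zero_junction", (), "zero_junction",
         "NO_JUNCTION_READS", False),
        (recipe.n_high_delta, "high_spanning_delta", (), "high_delta",
         "SPANNING_DELTA", False),
        (recipe.n_not_expressed, "not_expressed", (), "ok",
         "NOT_EXPRESSED", False),
    ]
    for count, cls, annots, read_mode, reason, in_final in specs:
        for i in range(count):
            gene_a, gene_b = state.new_gene(), state.new_gene()
            if cls == "not_expressed":
                state.silent_genes.update([gene_a, gene_b])
            else:
                state.expressed_genes.update([gene_a, gene_b])
            tokens = annots if annots is not None else (
                ARTIFACT_TOKENS[i % len(ARTIFACT_TOKENS)],
            )
            _plant(
                state, gene_a, gene_b, _pick_samples(state, 1),
                ("STARFUSION",), tokens, "in-frame", read_mode,
                cls, reason, in_final, None,
            )


def _plant_recurrent_pair(state: _State, annots: tuple[str, ...], cls: str,
                          in_final: bool, origin: str | None,
                          frame: str = "in-frame",
                          same_chrom: bool = False) -> None:
    gene_a = state.new_gene()
    gene_b = state.new_gene()
    if same_chrom:  # neighbouring genes, as in local rearrangements
        chrom = state.loci[gene_a][0]
        del state.loci[gene_b]
        state.allocate_locus(gene_b, chrom=chrom)
    state.expressed_genes.update([gene_a, gene_b])
    group = _pick_group(state)
    chosen = _pick_samples(state, 2, group=group)
    _plant(
        state, gene_a, gene_b, chosen, ("STARFUSION", "ARRIBA"),
        annots, frame, "ok", cls, "PASS", in_final, origin,
    )


def _plant_local_rearrangements(state: _State, recipe: CohortRecipe) -> None:
    for _ in range(recipe.n_local_rearrangements):
        _plant_recurrent_pair(
            state, ("LOCAL_REARRANGEMENT",), "local_rearrangement",
            False, None, same_chrom=True,
        )


def _plant_multifused(state: _State, recipe: CohortRecipe) -> None:
    for _ in range(recipe.n_multifused_sets):
        hub = state.new_gene()
        partners = [state.new_gene() for _ in range(5)]
        state.expressed_genes.update([hub] + partners)
        group = _pick_group(state)
        chosen = _pick_samples(state, 2, group=group)
        for partner in partners:
            _plant(
                state, hub, partner, chosen, ("STARFUSION", "ARRIBA"),
                (), "in-frame", "ok", "multifused", "PASS", False, None,
            )


def _plant_cross_group(state: _State, recipe: CohortRecipe) -> None:
    groups = sorted(set(state.group_of.values()))
    for i in range(recipe.n_cross_group):
        gene_a, gene_b = state.new_gene(), state.new_gene()
        state.expressed_genes.update([gene_a, gene_b])
        g1, g2 = groups[(2 * i) % len(groups)], groups[(2 * i + 1) % len(groups)]
        chosen = _pick_samples(state, 2, group=g1) + _pick_samples(state, 2, group=g2)
        _plant(
            state, gene_a, gene_b, chosen, ("STARFUSION", "ARRIBA"),
            (), "in-frame", "ok", "cross_group_ubiquitous", "PASS", False, None,
        )


def _plant_scavengeable(state: _State, recipe: CohortRecipe) -> None:
    for i in range(recipe.n_scavengeable):
        frame = "in-frame" if i % 2 == 0 else "frameshift"
        _plant_recurrent_pair(
            state, ("INTRACHROMOSOMAL",), "scavengeable_recurrent",
            True, "scavenged", frame=frame,
        )


def _plant_ubiquitous_drivers(state: _State, recipe: CohortRecipe) -> None:
    groups = sorted(set(state.group_of.values()))
    n_span = min(5, len(groups))
    in_final = n_span <= 4  # prevalence cutoff: removed only when > 4 groups
    for _ in range(recipe.n_ubiquitous_drivers):
        gene_a, gene_b = state.new_gene(), state.new_gene(oncogenic=True)
        state.expressed_genes.update([gene_a, gene_b])
        chosen = [
            _pick_samples(state, 1, group=g)[0] for g in groups[:n_span]
        ]
        _plant(
            state, gene_a, gene_b, chosen, ("STARFUSION", "ARRIBA"),
            (), "in-frame", "ok", "ubiquitous_driver", "PASS",
            in_final, "driver" if in_final else None,
        )


# ---------------------------------------------------------------------------
# File writers
# ---------------------------------------------------------------------------


def _write_tsv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    lines = ["\t".join(header)]
    lines += ["\t".join(row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


def _write_caller_files(state: _State, out: Path) -> None:
    for sample in state.samples:
        _write_tsv(
            out / f"{sample}.starfusion.tsv", STARFUSION_HEADER,
            state.caller_rows.get((sample, "STARFUSION"), []),
        )
        _write_tsv(
            out / f"{sample}.arriba.tsv", ARRIBA_HEADER,
            state.caller_rows.get((sample, "ARRIBA"), []),
        )


def _write_expression(state: _State, out: Path) -> None:
    genes = sorted(state.expressed_genes | state.silent_genes)
    rows = []
    for gene in genes:
        if gene in state.silent_genes:
            values = state.rng.uniform(0.05, 0.9, size=len(state.samples))
        else:
            values = state.rng.uniform(5.0, 50.0, size=len(state.samples))
        rows.append([gene] + [f"{v:.3f}" for v in values])
    _write_tsv(out / "expression.tsv", ["GeneSymbol"] + state.samples, rows)


def _write_references(state: _State, out: Path) -> None:
    gene_rows = [
        [gene, label]
        for gene in sorted(state.gene_labels)
        for label in sorted(state.gene_labels[gene])
    ]
    _write_tsv(out / "genelistreference.tsv", ["Gene_Symbol", "type"], gene_rows)

    fusion_rows = [
        [name, tag] for name, tag in sorted(state.fusion_tags.items())
    ]
    _write_tsv(out / "fusionreference.tsv", ["FusionName", "source"], fusion_rows)

    _write_tsv(
        out / "rescue_list.tsv", ["FusionName"],
        [[name] for name in sorted(set(state.rescue_names))],
    )

    # kinase domains on kinase-labeled genes, positioned in the distal half of
    # the gene body so the 3' breakpoint convention retains them
    domain_rows, exon_rows = [], []
    for gene in sorted(state.loci):
        chrom, start, strand = state.loci[gene]
        labels = state.gene_labels.get(gene, [])
        kinase = [lab for lab in labels if lab.startswith("kinase:")]
        if kinase:
            dom_lo = start + (30_000 if strand == "+" else 10_000)
            domain_rows.append(
                [gene, f"TX_{gene}_1", KINASE_PFAM, kinase[0].split(":", 1)[1],
                 chrom, str(dom_lo), str(dom_lo + 8_000), strand]
            )
        elif gene in NAMED_CAST_LABELS or int(state.rng.integers(0, 4)) == 0:
            dom_lo = start + 20_000
            domain_rows.append(
                [gene, f"TX_{gene}_1", "PF00536", "SAM_1",
                 chrom, str(dom_lo), str(dom_lo + 5_000), strand]
            )
        for e in range(3):
            exon_lo = start + e * 15_000
            exon_rows.append(
                [f"TX_{gene}_1", gene, chrom, str(exon_lo),
                 str(exon_lo + 2_000), strand]
            )
    _write_tsv(
        out / "domains.tsv",
        ["gene_symbol", "transcript_id", "pfam_id", "domain_name",
         "chrom", "start", "end", "strand"],
        domain_rows,
    )
    _write_tsv(
        out / "pfam_description.tsv", ["pfam_id", "name"],
        [[KINASE_PFAM, "Pkinase"], ["PF07714", "Pkinase_Tyr"],
         ["PF00536", "SAM_1"]],
    )
    _write_tsv(
        out / "exons.tsv",
        ["transcript_id", "gene_symbol", "chrom", "exon_start", "exon_end",
         "strand"],
        exon_rows,
    )


def _write_metadata(state: _State, out: Path) -> None:
    _write_tsv(
        out / "metadata.tsv", ["Sample", "group"],
        [[s, state.group_of[s]] for s in state.samples],
    )


# ---------------------------------------------------------------------------
# Manifest evaluation
# ---------------------------------------------------------------------------


def evaluate_against_manifest(
    cohort: pd.DataFrame,
    qc_reasons: pd.Series,
    final: pd.DataFrame,
    manifest: dict,
) -> dict:
    """Compare pipeline fates with the planted expectations.

    ``cohort`` is the standardized merged table (index = record id),
    ``qc_reasons`` the per-record terminal QC reason (index = record id),
    ``final`` the prioritized set with an ``origin`` column.  Returns per-class
    retention precision/recall, the overall per-record agreement fraction, an
    exact-match flag and the list of mismatches.  A pipeline record whose key
    is absent from the manifest raises an integrity error.
    """
    expected = {rec["key"]: rec for rec in manifest["records"]}

    def row_key(row: pd.Series) -> str:
        return _key(
            row["Sample"], row["FusionName"], row["Caller"],
            row["LeftBreakpoint"], row["RightBreakpoint"],
        )

    actual: dict[str, dict] = {}
    for record_id, row in cohort.iterrows():
        key = row_key(row)
        if key not in expected:
            raise ValueError(f"pipeline record not in manifest: {key}")
        actual[key] = {
            "qc_reason": qc_reasons.get(record_id, "PASS"),
            "in_final": False,
            "origin": None,
        }
    for _, row in final.iterrows():
        key = row_key(row)
        if key not in expected:
            raise ValueError(f"final-set record not in manifest: {key}")
        actual[key]["in_final"] = True
        actual[key]["origin"] = row["origin"]

    mismatches = []
    per_class: dict[str, dict[str, int]] = {}
    for key, exp in expected.items():
        got = actual.get(key)
        stats = per_class.setdefault(
            exp["class"], {"n": 0, "agree": 0, "tp": 0, "fp": 0, "fn": 0}
        )
        stats["n"] += 1
        if got is None:
            mismatches.append({"key": key, "expected": exp, "actual": None})
            if exp["in_final"]:
                stats["fn"] += 1
            continue
        agree = (
            got["qc_reason"] == exp["qc_reason"]
            and got["in_final"] == exp["in_final"]
            and (not exp["in_final"] or got["origin"] == exp["origin"])
        )
        if agree:
            stats["agree"] += 1
        else:
            mismatches.append({"key": key, "expected": exp, "actual": got})
        if got["in_final"] and exp["in_final"]:
            stats["tp"] += 1
        elif got["in_final"]:
            stats["fp"] += 1
        elif exp["in_final"]:
            stats["fn"] += 1

    n_total = sum(s["n"] for s in per_class.values())
    n_agree = sum(s["agree"] for s in per_class.values())
    summary = {}
    for cls, s in sorted(per_class.items()):
        precision = s["tp"] / (s["tp"] + s["fp"]) if (s["tp"] + s["fp"]) else None
        recall = s["tp"] / (s["tp"] + s["fn"]) if (s["tp"] + s["fn"]) else None
        summary[cls] = {
            "n_records": s["n"],
            "agreement": s["agree"] / s["n"],
            "retention_precision": precision,
            "retention_recall": recall,
        }
    return {
        "n_records": n_total,
        "agreement": n_agree / n_total if n_total else 1.0,
        "exact_match": not mismatches and len(actual) == len(expected),
        "per_class": summary,
        "mismatches": mismatches,
    }
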