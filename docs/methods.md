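# Methods

## Scope and data model

`fusioncurate` post-processes RNA fusion calls; it never touches reads or
alignments. Its inputs are the native TSVs of STAR-Fusion
(`star-fusion.fusion_predictions.tsv`) and Arriba (`fusions.tsv`), both
required to carry a FusionAnnotator `annots` column, a gene-level expression
matrix (FPKM or TPM, `GeneSymbol` column), and plain reference TSVs: gene
lists (`Gene_Symbol`, `type`), known-fusion lists (`FusionName`, `source`),
a rescue list of known oncogenic fusion names, PFAM domain genomic locations
and transcript/exon coordinates.

All records are standardized into one flat table with columns
`Sample, FusionName, Gene1A, Gene2A, Gene1B, Gene2B, LeftBreakpoint,
RightBreakpoint, LeftStrand, RightStrand, Fusion_Type, Caller,
JunctionReadCount, SpanningFragCount, Confidence, annots`. Coordinates are
1-based and fully closed; `chr` prefixes are stripped on ingest and only
re-added in plot labels. Gene symbols are compared case-sensitively after
trimming; no alias resolution is attempted. The TSV dialect is
tab-separated UTF-8 with `NA` (or empty) read as missing and `NA` written.

Caller-dialect mapping choices:

* STAR-Fusion `PROT_FUSION_TYPE` INFRAME → in-frame, FRAMESHIFT →
  frameshift, anything else → other; Arriba `reading_frame` in-frame →
  in-frame, out-of-frame → frameshift, `.` → other. Unknown vocabulary is
  logged and mapped to other, never a crash.
* Arriba does not report a single junction/spanning pair; we take
  `split_reads1 + split_reads2` as the junction read count and
  `discordant_mates` as the spanning fragment count. This sum rule is a
  convention of the standardized schema rather than something the callers
  document jointly, and is therefore called out here explicitly.
* Arriba breakpoint strings carry no per-breakpoint strand; strand is taken
  from the `strandN(gene/fusion)` columns when present (the fusion strand is
  authoritative) and recorded as `unknown` otherwise — we never invent an
  orientation.
* Multi-gene Arriba cells (`A,B`, `A(1234)`) are split; the first symbol
  populates `Gene1A`/`Gene1B`, the second `Gene2A`/`Gene2B`, distance
  suffixes stripped.
* Duplicate expression rows for one gene symbol collapse by the per-sample
  maximum — conservative against spurious "not expressed" removals.

## QC cascade

Four per-record stages with defaults: artifact alternation
`GTEx_recurrent_STARF2019|DGD_PARALOGS|Normal|BodyMap`, read-through filter
on, junction minimum 1, spanningDelta cutoff 100, expression minimum 1
(FPKM/TPM). Every stage emits one decision per record it sees (retained or
removed, reason, matched token), and the concatenated ledger is part of the
pipeline output; no record is dropped silently.

Design points worth knowing:

* Artifact matching is substring-per-token, not whole-cell regex, so the
  `Normal` alternative catches both `Greger_Normal` and `Babiceanu_Normal`.
  This can over-match user-supplied alternations (any token *containing* the
  alternative matches); the parameter is exposed and the behavior is pinned
  by tests.
* Read-through rescue accepts EITHER a `Mitelman` annotation token OR
  membership of the fusion name in the user-supplied rescue list; both
  routes lead to reason `READTHROUGH_RESCUED`. Rescue lives inside the
  read-through predicate, which makes the final retained set independent of
  stage order (verified by permutation tests).
* Read support removes at `JunctionReadCount < 1` and at
  `spanningDelta >= 100` exactly; the boundary (delta 99 retained, 100
  removed; junction 0 removed, 1 retained) is pinned by unit tests. When
  both conditions hold, the recorded reason is the junction one and the
  matched-token field lists both.
* The expression filter consults `Gene1A`/`Gene1B` only; secondary partners
  from multi-gene loci are ignored (and their presence logged). A gene
  absent from the matrix counts as not expressed; a sample absent from the
  matrix is an error, since silently passing every call of an uncovered
  sample would be misleading.
* Stages short-circuit (a removed record is not re-examined) for ledger
  clarity. Because each stage predicate is per-record and independent, the
  final retained set equals the input minus the union of flagged records
  under any stage order; tests assert set-equality under random
  permutations.

## Annotation

Partner labels come from the gene reference with a closed vocabulary
(`oncogene`, `tsg`, `kinase:<group>`, `tf_curated`, `tf_predicted`,
`cosmic`, `biotype:<name>`); a `kinase:<group>` label implies the bare
`kinase` category. The shipped synthetic reference includes the pediatric
additions (MYBL1, SNCAIP, FOXR2, TTYH1, TERT as oncogenes; BCOR, QKI as
tumor suppressors); production use replaces these files. Reciprocality is
per sample: a call is reciprocal iff the same sample also contains the
partner-swapped fusion name.

The z-score annotation is a deliberate hybrid: centered on the reference
MEDIAN but scaled by the sample standard deviation (n−1), i.e.
`z = (x − median_ref) / sd_ref`, flagged two-sided at |z| > 2 by default
(over- or under-expression). Genes with fewer than two reference values or
sd 0 get an undefined z, no flag, and a log entry. The reference matrix is
treated as opaque columns; whether it is a matched-tissue or pooled
reference is the user's choice.

## Domain retention

Domains are genomic intervals (1-based, closed, stranded) per gene and
optionally per transcript; multi-transcript genes are reported per
transcript with no canonical-transcript election. The 5′ partner keeps
sequence transcriptionally upstream of the left breakpoint (lower
coordinates on +, higher on −), the 3′ partner keeps downstream of the right
breakpoint; a domain is `retained` when wholly inside the kept region,
`partial` when the breakpoint falls inside it, `lost` otherwise, and
`unknown` only when the breakpoint cannot be compared (chromosome mismatch
or unparseable). A breakpoint exactly on a domain boundary retains that
boundary base (closed-interval convention). These semantics are pinned by a
12-cell truth table (2 partners × 2 strands × 3 placements) and checked
against a brute-force base-enumeration oracle on random instances.

Kinase-domain retention flags a partner true iff ANY kinase-family PFAM
domain of that gene is fully retained; `partial` is reported in a separate
flag and never promoted to retained, because a half-kinase-domain product is
a different biological claim.

## Cohort prioritization

Defaults: ≥ 2 callers for scavenging, ≥ 2 samples per group for recurrence,
scavenged fusions confined to 1 group, partner-promiscuity cutoff at ≥ 5
distinct partners per gene per sample, driver prevalence cutoff at > 4
groups. The promiscuity threshold is stated ambiguously in common usage
("more than 5" vs "default ≥ 5"); this package removes at ≥ 5 and exposes
the threshold. Group membership of a fusion is computed over the post-QC
cohort, before prioritization. The prevalence filter applies to the driver
branch only — the scavenged branch already enforces single-group
confinement. Recurrence counts distinct values of the configured sample
column; patients with multiple biospecimens are counted per biospecimen
unless the user supplies a patient-level column.

Drivers and scavenged records are disjoint by construction (scavenging
starts from the non-driver remainder, taken before prevalence filtering so
that prevalence-removed driver fusions are not scavenged back); the merge
deduplicates on (sample, fusion, caller, breakpoints) with driver origin
winning.

## Summaries, plots, report

Counting (intra-/inter-chromosomal, frames per caller, biotype / kinase
group / oncogenic category tallies, recurrence tables) happens on plain
tables; figures and the HTML report render those tables and make no
filtering decisions. A gene in several categories counts in each.
Recurrence tables rank by total distinct-count with lexicographic
tie-breaking (top 10 by default) so output is deterministic. The report is
plain HTML with TSV sidecars per embedded table, a parameter block, and
SHA-256 checksums of the inputs; it contains no timestamps, so its body is
byte-stable for fixed inputs. The reproducibility surface is the sidecar
tables, not figure pixels.

## Synthetic cohorts

The generator emulates caller-level outputs only — no FASTQ, no alignment.
Its default recipe is 10 groups × 10 samples with ~50 records per planted
class; each class violates exactly one rule (or none), covering every QC
reason and every prioritization branch, including a prevalence-removed
ubiquitous-driver class. Read counts are drawn from discrete uniform ranges
per class (clean records: junction 5–59, delta 0–49; high-delta records:
delta 100–199), expression from uniform 5–50 (silent genes 0.05–0.9)
FPKM-like units. Gene symbols and coordinates are synthetic apart from a
small named cast used in documentation; all coordinates, including the named
cast's, are invented. Randomness uses `numpy.random.default_rng(seed)` and
fixed iteration order, so identical recipe+seed produce byte-identical
files and manifest.

What passing the planted-truth check does and does not show: it verifies the
filter and prioritization logic end to end on records whose fates are known
by construction, with one violation per record. Real cohorts have correlated
violations, caller disagreement on breakpoints, messier annotation strings,
and expression matrices that do not cover every gene — the generator
exercises the missing-gene path but not the rest, so the planted check is a
logic test, not a sensitivity estimate on real data.

## Problem sizes and numerics

Tests and the acceptance script run the default recipe (584 records, 100
samples), 10,000 random domain-retention instances, and small closed-form
examples; the whole suite completes in seconds. Floating-point expression
values are compared against thresholds directly (no epsilon): the boundary
semantics are defined on the printed values, and the boundary tests use
exactly representable cases. Ledger reasons use a fixed vocabulary; ties in
recurrence tables break lexicographically; merge ordering is a stable sort
on (sample, fusion, caller).

## Known limitations

* Only STAR-Fusion and Arriba dialects are parsed; FusionAnnotator itself is
  consumed, not reimplemented.
* No alias/ortholog resolution of gene symbols; mismatched naming between
  fusion calls and the expression matrix silently looks like absence (by
  design the absence path treats the gene as not expressed).
* Domain retention is genomic-interval logic only; no protein-coordinate or
  structural modeling.
* The scavenge branch requires multi-caller cohorts; single-caller cohorts
  can only produce driver-branch output.
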