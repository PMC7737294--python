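# fusioncurate

Filtering and prioritization of putative oncogenic RNA fusions called from
bulk RNA-seq.

Fusion callers such as STAR-Fusion and Arriba report thousands of candidate
chimeric transcripts per cohort, most of which are transcriptional
read-throughs, homology-driven mis-mappings, or events also present in
healthy tissue. `fusioncurate` takes the callers' native output (pre-annotated
with FusionAnnotator so every call carries an `annots` tag list), merges it
into one standardized schema, removes artifacts with a transparent, fully
ledgered QC cascade, annotates gene partners against cancer gene lists and
PFAM domains, and prioritizes a final set of putative oncogenic fusions at
cohort level. It is aimed at cancer genomics analysts who need a
reproducible, scriptable post-processing step between fusion calling and
biological interpretation.

## Method

For each standardized call with junction read count $J$, spanning fragment
count $S$, partner genes $G_{1A}$ (5′) and $G_{1B}$ (3′) in sample $s$, the
QC cascade removes the call iff any of:

1. **artifact databases** — any annotation token matches the alternation
   `GTEx_recurrent_STARF2019|DGD_PARALOGS|Normal|BodyMap` (substring match
   per token, so `Greger_Normal` and `Babiceanu_Normal` are caught by
   `Normal`; `HGNC_GENEFAM` and `ConjoinG` are deliberately retained);
2. **read-throughs** — a `READTHRU`-style token is present *and* the fusion
   is not rescued as known oncogenic (no `Mitelman` token and not in the
   rescue list; e.g. P2RY8–CRLF2 is rescued);
3. **read support** — $J = 0$, or spanningDelta $= S - J \ge 100$;
4. **expression** — both $\mathrm{expr}(G_{1A}, s) < 1$ and
   $\mathrm{expr}(G_{1B}, s) < 1$ (FPKM or TPM).

Surviving calls are annotated (oncogene / tumor suppressor / kinase /
transcription factor / COSMIC labels per partner, known-fusion tags,
reciprocality per sample, optional expression z-scores
$z = (x - \mathrm{median}_{\mathrm{ref}})/\mathrm{sd}_{\mathrm{ref}}$
against a reference matrix) and prioritized in two branches:

* **drivers**: any partner carries a cancer gene-list label or the fusion is
  in the known-fusion reference; driver fusion names observed in more than 4
  groups (broad histologies) are removed as likely artifacts;
* **scavenged**: from the non-driver remainder, fusions called by ≥ 2
  algorithms, in-frame or frameshift, without `LOCAL_INVERSION` /
  `LOCAL_REARRANGEMENT` tags, recurrent in ≥ 2 samples of exactly one group,
  and without a partner fused to ≥ 5 distinct genes in a sample.

The union of the branches, origin-tagged, is the putative oncogenic set.
PFAM domain retention is computed in genomic coordinates: the 5′ partner
keeps sequence transcriptionally upstream of the left breakpoint, the 3′
partner keeps downstream of the right breakpoint, giving each domain a
retained / partial / lost status (kinase-domain retention is flagged per
partner).

## Worked example

The package ships a deterministic synthetic-cohort generator that emulates
caller outputs with a planted ground truth for every filter rule:

```bash
fusioncurate simulate --seed 42 --out cohort/
fusioncurate run --cohort-dir cohort/ --out-dir results/
```

which prints

```
generated 584 records in cohort/
outputs in results/: DomainRetention.tsv, FilterLedger.tsv, FilteredFusionCalls.tsv, PutativeDriverFusions.tsv, StandardizedFusionCalls.tsv
```

The 584 caller records across 100 samples (10 groups × 10 samples) shrink to
334 QC survivors and a final putative oncogenic set of 148 records:
planted driver fusions (e.g. a KIAA1549--BRAF-style event with its kinase
domain retained in the 3′ partner), rescued oncogenic read-throughs, and
scavenged recurrent fusions; planted artifacts, plain read-throughs,
unsupported and non-expressed calls are removed with their reasons recorded
per record in `FilterLedger.tsv`.

The same steps are available as library functions
(`fusion_standardization`, `fusion_filtering_QC`, `annotate_fusion_calls`,
`zscored_annotation`, `get_pfam_domain`, `prioritize`, ...) and as
step-by-step CLI commands (`standardize`, `qc`, `annotate`, `prioritize`,
`simulate`, `run`).

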