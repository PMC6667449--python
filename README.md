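# splicecat

Build cross-sample catalogs of transcript variants for large multi-exon
receptor genes (adhesion GPCR-style loci) from assembled-transcript GTFs,
and turn them into classified protein products, validation reports and
condensed locus figures.

The pipeline:

1. **Exon catalog** — merges exons observed across samples into role-aware
   equivalence classes (first exons by 3' splice donor, last exons by 5'
   splice acceptor, internal exons by exact coordinates; strand-aware) and
   encodes every transcript as a numeric exon-class sequence. Counts TSS and
   scores novelty against a reference exon annotation.
2. **Quantification** — derives the FPKM working cutoff from per-sample
   medians (0.42 averaged median → 0.5), applies library/gene inclusion
   gates, computes per-tissue variant fractions, and keeps variants with a
   tissue-mean fraction ≥ 1% in at least one tissue.
3. **ORF / protein** — splices exon sequences into mRNA, translates the
   longest AUG-initiated reading frame, projects the CDS back onto the
   genome, overlays protein domains by coding-base coverage, and classifies
   each product (full receptor, soluble NTF, membrane-anchored NTF, CTF,
   other) plus per-gene variability flags. Extracts exon–intron architecture
   signatures of a coding region as (codon offset, phase) intron lists.
4. **Validation** — NTF/CTF coverage-asymmetry testing on bedGraph tracks
   (percentile exclusion + two-sided Mann–Whitney) and exon-chain matching
   of BED12 long reads against predicted variants
   (IDENTICAL/TRUNCATED/SKIPPED_EXON/NOVEL_EXON/NO_MATCH).
5. **Reporting** — per-gene summary rows, cohort aggregates, flag-matrix
   percentages, knockout residual-transcript reports (which variants survive
   an exon deletion, in-frame vs frameshift), and deterministic
   condensed-intron locus plots (true exon widths, fixed-width introns,
   thick CDS / thin UTR, grey domain columns, abundance color bins).
6. **Synthetic data** — ground-truthed loci, variant sets, replicate
   expression (Dirichlet tissue truth + logistic-normal jitter), coverage
   tracks with a planted NTF/CTF fold, and full-length/truncated long
   reads; all pure functions of (spec, seed).

## CLI

```bash
# ground-truthed synthetic bundle (FASTA, GTFs, domains, reads, coverage, truth)
splicecat simulate --seed 3 --out demo/

# exon catalog + signatures + browser BED track
splicecat catalog --gtf demo/vat_rep1.gtf --gtf demo/vat_rep2.gtf \
    --gtf demo/vat_rep3.gtf --gene GENE1 \
    --reference-exons demo/reference_exons.tsv --out out/

# abundance fractions, product classification, validation, summary, figure
splicecat quantify  ... --min-fraction 0.01
splicecat classify  ... --genome demo/genome.fa --domains demo/domains.tsv
splicecat validate  ... --reads demo/longreads.bed --coverage demo/coverage.bedgraph
splicecat report    ...
splicecat plot      ... --genome demo/genome.fa --format svg
```

All commands accept `--config FILE` (flat `key = value`, overridden by
flags) and write a `manifest.json` with the parameters used. Thresholds:
`--min-fraction` (default 0.01), `--fpkm-cutoff` (0.5), `--min-codons`
(30); `validate` adds `--percentile` (1) and `--end-tolerance` (10).

## Layout

```
src/splicecat/
  core_io.py        types + GTF/FASTA/BED12/bedGraph/TSV readers & writers
  exon_catalog.py   exon equivalence classes, signatures, novelty, condensation
  quantification.py cutoff derivation, inclusion gates, fractions, 1% filter
  orf_protein.py    spliced mRNA, longest ORF, domains, product taxonomy
  validation.py     coverage asymmetry, long-read chain matching
  reporting.py      summary rows, cohort stats, knockout report, locus plot
  synthetic.py      seeded ground-truth generators
  pipeline.py       per-gene orchestration shared by CLI/tests
  cli.py            click subcommands
  fixtures/         packaged per-gene summary and variability-flag tables
tests/              pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py
```

Internal coordinates are 0-based half-open everywhere; conversion happens
only at format boundaries (GTF 1-based inclusive, BED 0-based).
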