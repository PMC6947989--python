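# mencrna

Linking fine-mapped GWAS risk variants to multi-exonic non-coding RNAs
(mencRNAs) annotated by targeted RNA capture around risk loci.

Most trait-associated variants found by GWAS are non-coding. After
fine-mapping, each independent risk signal yields a set of **credible causal
variants (CCVs)** — the variants whose association p-values lie within two
orders of magnitude of the signal's lead variant (p ≤ 100 · p_lead). This
package implements the computational analysis that asks whether such CCVs
act through non-coding RNA genes transcribed from the captured intervals
around the signals, and which genes they plausibly target. It is written
for statistical geneticists and regulatory-genomics analysts who want a
tested, seeded, fully synthetic-data-exercisable version of that pipeline.

## What it computes

**Feature-restricted enrichment.** For a feature class *F* (mencRNA exons,
introns or promoters) inside the capture universe *U* (the union of the
1.5-Mb capture regions), the fold enrichment is

    fold = ( |CCV ∩ F| / |CCV| ) / ( bp(F ∩ U) / bp(U) )

Significance comes from two routes: a base-pair hypergeometric test
(drawing |CCV| positions without replacement from bp(U) of which bp(F∩U)
are feature bp), and an **empirical circular-permutation test**: every
transcript's annotations are rotated by a uniform random offset around its
circularized capture region — preserving the sizes and relative positions
of all features of the transcript — while the CCVs stay fixed; the
empirical p is the fraction of rotations with overlap ≥ observed.

**Three-route target linkage.** A gene is a candidate target of a signal
when a CCV falls (1) in a gene exon, (2) in a gene promoter (TSS ± 500 bp),
or (3) in one anchor of a chromatin loop whose other anchor overlaps a
gene promoter. Genes supported by ≥ 2 independent signals are reported as
multi-signal targets.

**cis-eQTL screen.** Expression is log2-transformed and quantile
normalized; each (gene, variant) pair sharing a capture region is tested by
OLS of expression on additive dosage plus covariates (always including the
gene's copy-number estimate); discoveries are controlled at BH FDR < 5%.
An eQTL gene *overlaps* a risk signal when some CCV's eQTL p is within two
orders of magnitude of the top eQTL variant's p.

**Expression metrics.** Tissue specificity per gene,
τ = Σᵢ (1 − xᵢ/x_max)/(N − 1) on log2(x+1) tissue means (0 = broad,
1 = single-tissue), and a Mann–Whitney comparison of |r| between
loop-connected and non-connected mencRNA–mRNA pairs within 1 Mb.

**Capture QC.** ERCC spike-in dose–response regression (log2 FPKM vs log2
concentration), lower/upper limits of detection at the FPKM 0.5 threshold,
capture fold enrichment from the two regression lines, and a paired-t
specificity test on targeted vs non-targeted gene fold changes.

Every input the pipeline consumes can be generated by the seeded
`mencrna.simulate` module, which records its ground truth (planted CCV
sets, planted linkage triples, planted eQTL betas, planted dose–response
lines) in a JSON manifest.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_ccv_enrichment.py
```

prints (seed 1 bundle, 10,000 rotations):

```
77 CCVs across 15 signals; 200 mencRNA genes
  exon      observed   2  expected   1.50 [1.48, 1.53]  fold  1.30  p_emp 0.4409  p_hyp 0.456
  intron    observed   3  expected   7.70 [7.65, 7.76]  fold  0.37  p_emp 0.9891  p_hyp 0.99
  promoter  observed   1  expected   0.52 [0.50, 0.53]  fold  1.95  p_emp 0.4098  p_hyp 0.403
```

The bundle places CCVs uniformly (exon-placement odds 1), so none of the
three features is enriched: the observed overlaps sit inside the
permutation nulls and both p-values agree. Rerunning `01_simulate_cohort`
with `ccv_exon_enrichment: 3` in a config drives the exon row significant
while introns and promoters stay null. The remaining drivers
(`03_linkage`, `04_eqtl`, `05_expression_metrics`, `06_capture_qc`) link
CCVs to their planted target genes (18/18 triples, 0 false positives on
the seed-1 bundle), recover planted cis effects, separate the planted
broad/specific τ regimes (medians 0.090 vs 1.000), and read the planted
capture enrichment (~300×) off the ERCC lines.

The same stages are scriptable through the CLI
(`mencrna simulate | enrich | link | eqtl | tau | correlate | capture-qc |
run-all`) or the `mencrna.pipeline.run_end_to_end` entry point with a YAML
config; all tabular outputs are deterministic TSV/BED/GTF/BEDPE text.

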