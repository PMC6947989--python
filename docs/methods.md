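# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical decisions taken where the design was open.

## Coordinates and gene models

All positional arithmetic is 0-based half-open. BED and BEDPE are read
natively; GTF is converted from 1-based inclusive on read and back on
write. Variants are points (`[pos, pos+1)`); indels are out of scope.

A gene model is one or more transcripts, each an ordered chain of
non-overlapping exons on one chromosome and strand. Introns are exactly
the gaps between consecutive exons, so exon ∪ intron reconstructs the
transcript span. Two promoter definitions coexist because the analysis
uses both:

* `upstream500` — the 500 bp strictly upstream of the strand-aware TSS
  (used by the enrichment stage; requires a strand);
* `flank500` — TSS ± 500 bp, 1001 bp total (used by the promoter and loop
  linkage routes, where the interaction data is effectively unstranded
  about the TSS).

Promoters are truncated at position 0 and skipped (with a warning) if
fully clipped. Multi-transcript genes have one promoter per transcript;
gene-level queries union them.

## Captured-transcript filters

A captured gene is retained iff it is multi-exonic, overlaps the capture
universe by ≥ 1 bp, has no same-strand exonic overlap with a
protein-coding exon, and reaches max FPKM ≥ 0.5 in some library; isoforms
with max FPKM < 0.01 are dropped. When merging the captured annotation
with a reference annotation, an overlapping captured gene below max FPKM
0.5 yields to the reference gene and otherwise supersedes it; captured
genes with ≥ 1 bp opposite-strand coding-exon overlap are excluded
outright because unstranded downstream quantification cannot attribute
reads between them. The filter is idempotent and every removal is logged
with a reason code.

The capture filter's "overlapping protein-coding sequences" is
implemented as *same-strand* exonic overlap: the opposite-strand rule is
stated separately for the unstranded merge, so reading the first rule as
same-strand keeps the two rules distinct rather than redundant.

## CCV sets

A signal's credible causal variants are the variants with
p ≤ 100 · p_lead. The boundary is inclusive (a variant at exactly 100×
qualifies): "within two orders of magnitude" is ambiguous at the boundary
and the inclusive reading is deterministic. The lead is the argmin-p
variant, ties broken lexicographically by variant id and logged.

## Enrichment statistics

Fold enrichment divides the CCV overlap proportion by the feature's
coverage fraction inside the capture universe. CCVs outside the universe
are dropped with a warning count. `fold = 0` when overlap and coverage are
both zero (no evidence); an infinite sentinel (with a warning) flags the
inconsistent case of overlap without coverage.

The hypergeometric test treats base pairs within the universe as the
population: an upper-tail p for ≥ k of n CCV positions landing in the
feature's bp, drawn without replacement. The bp-unit population is a
committed definition — contingency-table variants exist but the bp unit
matches the fold-enrichment denominator.

### Circular permutation

The empirical null rotates annotations, keeping CCVs fixed. Each capture
region is circularized independently; every transcript is assigned to the
region containing its 5′-most feature base (a transcript spanning two
regions is an error, one longer than its region likewise) and all its
features shift together by one uniform offset δ ∈ [0, L), wrapping modulo
the region length — so feature sizes, intra-transcript spacing, and the
per-region annotation budget are all preserved. Transcripts shift
independently, one offset stream per transcript. Features that poke
outside their region (clipped promoters at region edges) are clipped to
the region before rotation.

Offsets come from counter-based Philox streams keyed on
`(seed, crc32(transcript_id))`, so results are independent of iteration
order and exactly replayable. The implementation never materializes
rotated intervals in the hot loop: for each (CCV, transcript) pair it
precomputes the set of offsets that would cover the CCV — for a feature
`[s, e)` and CCV at relative position p this is the interval
`(p − e, p − s]` mod L, one offset window per feature, disjoint because
exons are — and tests membership by sorted-boundary parity, vectorized
over all permutations. A materializing `permute_annotation` exists as the
slow reference path; tests assert the two routes agree rotation-for-
rotation, and on single-transcript regions small enough to enumerate all
L rotations the Monte-Carlo p matches the exact p within binomial error.

The empirical p is the raw ratio `#{overlap ≥ observed}/n` (an add-one
correction is available but off by default, matching the ratio-of-counts
definition). The 95% CI of the permutation mean is the normal
approximation mean ± 1.96·SE; with n = 10⁵ the CI is narrow and the
approximation is immaterial. The observed overlap is computed through the
same offset-window machinery at δ = 0, guaranteeing observed and
permuted counts use identical geometry.

## eQTL scan

Expression: log2(x + pseudocount) with pseudocount 1 (unstated upstream;
1 keeps zeros at zero), then quantile normalization across samples —
every sample's sorted values are replaced by the cross-sample mean of
order statistics, ties receiving the mean of their tied ranks' reference
values. Tie-free samples carry exactly the reference distribution
afterwards (asserted); tied entries necessarily perturb it.

Each (gene, variant) pair with the variant in the gene's capture region
(no extra distance cutoff — the capture region *is* the cis window) is
fitted by OLS: expression ~ 1 + dosage + covariates, with the gene's
copy-number estimate always included for tumor-style data. Beta, SE and
the two-sided t-test p come from the closed-form normal equations;
rank-deficient designs and monomorphic variants are skipped with a log
entry. The closed form is cross-checked against statsmodels OLS in the
test suite. FDR is Benjamini–Hochberg over all tests in the run (global
rather than per-gene — the broader family is the conservative reading),
significant at q < 0.05.

The signal-overlap rule mirrors the CCV definition on the eQTL side: the
gene's association overlaps a signal iff some CCV's eQTL p is within two
orders of magnitude of the top eQTL variant's p. Colocalization proper is
out of scope; this screen is the implemented surrogate.

## Linkage routes

Exon and promoter routes intersect CCV points with per-gene feature
unions. The loop route fires when one anchor overlaps (≥ 1 bp) a gene
promoter (flank500) and the other contains ≥ 1 CCV; it is symmetric in
anchor order, evaluates both orientations when anchors overlap each other
(warned), and emits one record per (gene, signal, loop, cell line).
Multi-signal targets deduplicate across loops and cell lines and report
genes whose records span ≥ 2 *distinct signals* — the headline
"two or more independent CCVs" is read as multi-signal support, since a
single signal's CCVs are correlated through LD and would not constitute
independent evidence (a same-signal mode exists behind a flag). Loop
anchors are used exactly as provided; no padding is added.

The promoter route uses flank500 by default, consistent with the loop
stage's ±500 bp promoter definition; the enrichment stage keeps
upstream500. Both stages accept either mode.

## Expression metrics

τ uses the standard specificity formula on log2(x+1)-transformed tissue
means; all-zero genes are reported missing. τ is scale-invariant and
rises as expression concentrates. The co-expression filter keeps genes
nonzero in ≥ 20% of samples with raw MAD ≥ 1 (no 1.4826 consistency
factor — the plain definition). Looped-pair analysis forms all
mencRNA × coding pairs with TSS-to-TSS distance ≤ 1 Mb, marks a pair
looped when any loop (cell lines pooled) joins the two promoters, uses
Pearson correlation on normalized expression (Spearman via flag), and
compares |r| between groups with a two-sided Mann–Whitney U test (the
group comparison is a location question on a bounded, non-normal
statistic; the rank test needs no distributional assumption).

## Capture QC

Dose–response fits are OLS of log2 FPKM on log2 concentration over
detected spike-ins, "detected" meaning FPKM ≥ 0.5 — the same threshold as
the LLD, there being no reason to use two detection rules. The LLD is the
smallest concentration reaching the threshold. The ULD is a flagged
heuristic (no standard definition exists): the highest concentration
before the residual drops > 2 residual-SDs below the fitted line. Capture
fold enrichment is 2^(Δ predicted log2 FPKM) at a stated concentration;
because unequal slopes make the ratio concentration-dependent, the
pipeline reports it at the geometric mean of the shared detected
concentrations together with both endpoints. The specificity test is a
two-sided paired t on log fold changes; zero-variance differences are
degenerate and reported as p → 0 with a warning.

## Synthetic data

The generators emulate the statistical structure each stage assumes, at
desk scale. Defaults: 10 regions × 1.5 Mb (the real design tiles ~139
such intervals); 20 mencRNA genes + 4 protein-coding decoys per region
(the real catalog averages ~29 mencRNAs per region); 2–6 exons of
150–600 bp with 0.5–5 kb introns (two-exon transcripts dominate real
capture data); 15 signals × 30 variants with 1–10 CCVs per signal (most
real signals have ≤ 10); lead p log-uniform in [1e−12, 1e−8]; follower
CCV p in [p_lead, 100·p_lead] and non-CCV p in [200·p_lead, 1e5·p_lead],
so the two-orders rule recovers exactly the planted set; MAF uniform
[0.05, 0.5]; dosage binomial(2, MAF); expression = baseline +
β·dosage + 0.5·copy-number + N(0, 1) on the log-normalized scale;
7 tissues; 92 ERCC transcripts on a log2 concentration ladder with the
captured line's intercept 8.23 log2 units (≈ 300×) above the
non-captured one.

CCV exonic placement uses odds-weighted bp sampling: exonic bp get weight
*e* (`ccv_exon_enrichment`), everything else weight 1, so
P(exonic) = eC/(eC + 1 − C) at coverage C — analytically checkable, and
e = 1 is the uniform null used for calibration. Loops are planted as
promoter-anchor/CCV-anchor pairs (4-kb anchors) plus random decoys. The
ground-truth manifest's linkage triples are derived by an independent
plain-loop geometry scan inside the generator, so end-to-end recovery
tests compare two implementations of the route rules.

What the generators do **not** emulate: LD structure within signals
(variants are placed independently), sequence content (no reads, no GC),
overlapping or nested genes, multi-isoform genes, population structure or
ancestry covariates in the eQTL stage, and cell-type-specific loop sets.
Passing tests therefore demonstrate correctness of the statistics and
plumbing under the stated generative model, not robustness to LD-driven
clustering or annotation pathologies of real data — the circular
permutation is precisely the device that would absorb positional
clustering in real annotations, and its structure-preservation is tested
directly.

## Numerical and scale choices

Problem sizes in the test and acceptance runs are chosen to keep the full
suite in the low minutes on one CPU: calibration uses 100 cohorts × 2,000
rotations, power 50 cohorts at exon coverage ~5% with ≥ 100 CCVs
(25 genes/region, 4–8 exons of 300–700 bp, 20 signals × 5–10 CCVs), the
null-FDR check 200 seeds of a 4-region cohort, and sensitivity one cohort
at β = 0.8, n = 500. Production runs default to 10⁵ permutations; the
permutation engine is O(pairs × log-boundaries) per rotation batch, so
10⁵ rotations on the default cohort take seconds.

Degenerate inputs are errors, not silent defaults: empty universes, empty
signals, transcripts longer than their region, rank-deficient designs,
fewer than three detected spike-ins. Everything stochastic takes an
explicit seed, and identical seed + config reruns are byte-identical
(hash-compared in tests); run manifests record the seed and a hash of the
analysis configuration (excluding output paths).

## Known limitations

* The empirical p has resolution 1/n and can be 0 at raw-ratio settings;
  use the add-one flag when downstream consumers need p > 0.
* The per-region circularization treats regions as independent; a
  transcript genuinely spanning two merged capture regions is rejected
  rather than rotated jointly.
* The ULD heuristic is sensitive to the residual SD when saturation is
  mild.
* The eQTL stage fits one variant at a time (marginal, additive); no
  conditional analysis or mixed models.
* The LLD read off a log2 concentration ladder is quantized to ladder
  steps, so planted detection-limit ratios are recovered up to one step.
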