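# Methods

`lincscout` implements a discovery-and-refinement analysis for long
intergenic non-coding RNAs (lincRNAs): filter an assembled transcriptome to
putative lincRNAs, learn a classifier of TSS proximal regions from sequence
and chromatin features, scan the genome for candidate regions, correct
truncated 5' ends against them, and annotate lincRNAs by co-expression
("guilt by association") GSEA.  This note records the models, the tunable
parameters and why they hold their defaults, the synthetic data the test
suite runs on, and the numerical choices made where the design was open.

## Coordinates and core types

All internal coordinates are 0-based half-open; GTF (1-based inclusive) is
converted at the reader/writer boundary and nowhere else.  A transcript's
TSS is the first transcribed base: `first_exon.start` on the plus strand,
`last_exon.end - 1` on the minus strand.  The TSS proximal region is the
interval from 1 kb upstream to 0.5 kb downstream of a TSS — 1,500 bp, the
same span as one genome-scan window ([tss-1000, tss+500) on the plus
strand, the mirror on the minus strand).

## Candidate filter

Five ordered steps reduce the assembled transcriptome to putative
lincRNAs; each elimination is recorded with its reason:

1. **Annotation overlap** — remove any transcript sharing >= 1 bp of exonic
   overlap with a known transcript, on either strand.  lincRNAs are
   intergenic by definition, so either-strand exon overlap is the
   conservative default; same-strand-only and gene-span-level comparisons
   are exposed as options.
2. **Size and 5' support** — keep spliced length >= 200 nt; single-exon
   survivors additionally need a CAGE peak overlapping the strand-aware
   window [TSS-1000, TSS] (closed at the TSS base).  The length gate is
   inclusive (>= 200).
3. **ORF filter** — keep transcripts whose longest ORF is < 300 nt.  The
   ORF is ATG through an in-frame stop, inclusive, scanned over the three
   forward frames of the mature transcript; codons containing N neither
   start, extend, nor stop an ORF, while N bases still count toward
   transcript length.
4. **Expression** — keep mean FPKM >= 1 across the expression table's
   samples (the samples stand in for ESC replicates).
5. **Coding potential** — keep score <= 0.44; the score is consumed as an
   input column (e.g. a CPAT-style coding probability), never computed here.

## Region features

Each 1,500 bp region is described by 350 features:

- 336 k-mer frequencies (k = 2, 3, 4; counts over valid windows, windows
  containing N excluded from numerator and denominator);
- CpG observed/expected ratio, (N_CG x L) / (N_C x N_G), 0 when C or G is
  absent;
- CpG-island and repeat coverage fractions (repeats exclude the simple
  repeat, low-complexity and satellite classes, matched on interval names);
- one presence flag per library motif — both strands scanned with log-odds
  PWM scores (pseudocount 0.01), presence when the best hit's exact
  background p-value is <= 1e-4;
- mean CAGE signal and mean PolII/H3K4me3/H3K9ac/H3K27ac signal over the
  region.

Minus-strand region sequences are reverse-complemented before sequence
featurization so features are promoter-oriented.  Genome-scan windows are
featurized in the plus orientation (their strand is unknown); the planted
promoter signals (CpG content, double-stranded motif scanning, coverage and
signal means) are close to orientation-symmetric, so this costs little.
A vectorized scanner (`WindowScanner`) produces bit-identical values to the
per-region path on N-free plus-strand windows; the equality is asserted in
the test suite.

PWM hit p-values come from the exact distribution of the discretized
log-odds score under a 0-order background, built by one convolution per
motif column (granularity 1e-3).  This makes motif presence deterministic
and self-contained; the q-value-based occurrence rule used with external
scanners is approximated by Benjamini-Hochberg over best-hit p-values when
enrichment across a motif library is computed.

## TSS proximal region classifier

**Training set.**  Positives are the TSS proximal regions of reference
lincRNAs expressed at FPKM >= 0.5.  Negatives are 1,500 bp windows sampled
uniformly (seeded) within +-10 kb of each positive TSS, rejecting windows
that overlap any annotated exon or any positive region; the default ratio
is one negative per positive (configurable), and a TSS with no valid
negative after 200 draws is dropped with a warning.

**Model.**  An RBF-kernel SVM with gamma = 1 and cost C = 2.  Features are
standardized inside each training fold, and gamma is applied to the
*dimension-averaged* squared distance — implemented as an effective kernel
coefficient gamma / n_features.  With ~350 standardized features a raw
exp(-||dz||^2) underflows for every pair of points (typical ||dz||^2 is
about 2 x 350), collapsing the decision function to a constant; averaging
over dimensions keeps the stated (gamma, C) meaningful for every feature
subset, and reduces exactly to gamma = 1 for a single-feature group.

**Evaluation.**  Stratified 10-fold cross-validation (seeded shuffle;
standardization refit per fold).  Reported: accuracy, error rate (their sum
is 1 by construction), sensitivity, specificity, precision, AUROC and
AUPRC from the pooled out-of-fold decision scores, plus per-fold values and
the pooled ROC/PRC curves.  An ablation harness fits the same model per
feature group (k-mer; histone = PolII + 3 marks; CAGE; motif; CGI + CpG
o/e; repeat; all) to reproduce the structure of the per-category
comparison.

**Genome scan.**  Windows of 1,500 bp tile each chromosome at a 300 bp
step; windows overlapping annotated exons are excluded; remaining windows
are scored and those with positive decision value are kept (the raw
windows are the downstream input; a merged track is emitted for browsing
only).  The decision threshold is the SVM's sign — no threshold tuning.

## 5'-end correction

Every predicted region carries an anchor — the point 1,000 bp into the
region on the transcript's strand (`start + 1000` on plus, `end - 1001` on
minus): the new-TSS candidate.  For a transcript with TSS t, candidates are
regions whose anchor lies in the strand-aware window [t - 1000, t]; the
anchor closest to t wins, ties break upstream, and an anchor at exactly t
wins at distance zero and changes nothing — which is what makes correction
idempotent.  The first exon is extended genomically to the winning anchor
(no new splice sites); downstream exon structure is untouched, and a TSS is
never moved downstream.  Evaluation pairs TSS meta-profiles (CAGE, DHS,
histone marks) and nearest-CAGE-peak distance distributions before and
after correction.

## Guilt-by-association annotation

For each lincRNA expressed at FPKM >= 0.5, coding genes (FPKM >= 0.5) are
ranked by Pearson correlation on log2(FPKM + 1) (Spearman by flag; ties
break by gene id).  A gene set's enrichment score is the signed maximum
deviation of the weighted Kolmogorov-Smirnov running sum: hits increment by
|r|^p / sum_hits |r|^p with p = 1, misses decrement by 1 / (N - N_hits).
Significance is a permutation family-wise error rate: gene labels of the
ranked list are permuted 1,000 times (the only well-defined scheme when a
single ranked list exists per lincRNA), ES is recomputed for every term,
and a term's FWER p is the fraction of permutations whose maximum ES across
terms (positive side — guilt by association targets positive co-expression)
reaches its observed ES.  Terms with FWER p < 0.05 are reported; gene sets
are restricted to 5-500 genes after intersection with the ranked list;
max-statistic dominance (FWER p >= per-term p) is asserted on every run.
Permutation p-values are exact counts (multiples of 1/n_perm; no +1
smoothing) so their distributional properties stay testable.

## Sparse k-mer selection (SCAD)

The discriminative k-mer search fits a linear classifier under the squared
hinge loss with the SCAD penalty (concavity a = 3.7): lambda|w| up to
lambda, a quadratic blend to a*lambda, constant beyond — continuous, with
the published piecewise derivative.  Optimization is by local linear
approximation: each outer step replaces the penalty with a weighted L1 term
at the current iterate (weights = SCAD derivative) and solves it with FISTA
proximal gradient (4 LLA steps, warm-started along a 20-point log-spaced
lambda path).  Lambda is chosen by 5-fold stratified CV on
misclassification error with the one-standard-error rule — the largest
lambda whose error is within one SE of the minimum — which favours the
sparsest support statistically indistinguishable from the best, matching
the "least error rate" selection target.  Motif enrichment between classes
is a two-tailed Fisher exact test per motif with BH control across motifs
(selected at FDR < 0.01).

## Comparative sequence analyses

Sliding profiles aggregate any per-window scalar (palindrome coverage, CGI
or repeat coverage, CpG o/e) over 300 bp windows stepped by 50 bp around
TSS anchors, minus-strand anchors flipped, with a seeded bootstrap
(resampling regions, 1,000 replicates) giving 5-95% bands.  Palindromes are
exact reverse-complement palindromes, even length, no spacer, default
length 6-24, reported at their maximal extension; the profile statistic is
the fraction of window bases inside a palindrome.  Obs/Exp word analysis
compares each set's word frequency to the expectation from that set's
pooled mononucleotide composition; words whose between-set fold change
exceeds 1.2 or falls below 0.8 are retained.  (Those gates are slightly
asymmetric — exact swap symmetry would need lo = 1/hi; the published gates
are kept.)  Meta-transcript coverage resamples each transcript's exonic
per-base signal to 100 length-normalized bins (bin 1 = 5' end) and
averages; TSS meta-profiles default to a +-2 kb flank (unstated upstream
choices are configurable).  CAGE peak positions default to the interval
midpoint (no summit column in BED), configurable to the 5' edge; nearest
peaks tie toward upstream, since the analysis exists to extend 5' ends.

## Synthetic worlds

The generator builds the data regime the analysis assumes, with ground
truth for recovery tests.  Defaults: 30 coding loci, 50 "known" lincRNAs
(in the annotation with their true TSS — the training reference), 40
"novel" lincRNAs (present only in the assembly; the discovery/correction
targets), on two chromosomes of ~1.5 Mb each, loci separated by >= 21 kb so
negative-sampling zones stay clean.

- **Sequence**: i.i.d. background at GC 0.42 with 75% of background CpG
  dinucleotides broken (background CpG o/e ~0.34); promoters ([-1000,+500)
  of each true TSS) receive planted CG pairs at 0.04/bp (promoter CpG o/e
  ~1.0) and two motif instances sampled from a six-PWM synthetic library of
  GC-rich promoter consensus motifs, placed in [-600, +100], random strand.
- **ORFs**: coding transcripts carry a planted 396 nt ORF; lincRNA mature
  sequences are depleted of start codons (ATG -> ATC) so the ORF filter is
  clean by construction.
- **Signal**: each chromatin mark is Poisson background (0.2/bp) plus a
  symmetric exponential bump at every true TSS (decay 300 bp; summit 12
  tags/bp scaled per mark; lincRNA promoters at 0.6x, mirroring their
  weaker marks); CAGE is a sharp bump (decay 25 bp, summit 40) at a peak
  summit jittered within +-30 bp of the true TSS, with a 30 bp peak
  interval per locus.
- **Annotations**: a CGI spans each TSS +-400 bp plus background CGIs away
  from promoters; repeats cover ~15% of the genome outside +-1.6 kb of any
  TSS.
- **Assembly**: assembled transcripts are copies of the true loci with the
  5' end moved downstream by U(100, 1000) bp (clamped to leave >= 150 bp of
  first exon); the exact truncation per transcript is recorded as truth.
- **Expression**: log-normal FPKM, ln-scale mean 2.5 for coding vs 0.8 for
  lincRNA (sigma 0.8; 12 samples with 0.3 multiplicative sample noise), so
  lincRNAs sit well below coding genes and a realistic fraction falls under
  the FPKM gates.
- **Co-expression worlds** for annotation tests: 300 genes x 20 samples of
  log-normal expression and 50 GO-style gene sets; a planted association
  adds a shared latent factor (effect 1.5) to one set's members and the
  query lincRNA.

All randomness flows from one seeded generator; a fixed seed reproduces a
world byte for byte.  What the generator does **not** emulate: splice
isoform diversity, sequencing reads, enhancer-like background chromatin
peaks, repeat families with real sequence content, GC-dependent coverage
bias, or any correlation between expression level and signal strength.
Passing tests therefore demonstrate the machinery recovers planted
structure under the stated statistical assumptions — not performance on
real genomes.

## Problem sizes

The test suite and the acceptance script run the full pipeline on the
default world (120 loci, ~3 Mb, ~10,000 scan windows, 50 + 50 training
regions), five additional seeds for the feature-group ablation, a planted
2-of-52 SCAD recovery at n = 400, and ten null co-expression worlds for
GSEA calibration; the whole suite completes in about a minute on one CPU.

## Known limitations

- **Correction resolution is bounded by the closest-region rule.**  Because
  training negatives may not overlap positive regions, the classifier never
  sees windows that partially overlap a promoter, and every feature is a
  window mean, (piecewise-)linear in the overlap fraction; the balanced SVM
  therefore classifies windows positive out to roughly half a window
  (+-700 bp) around a true promoter.  The correction rule picks the
  candidate anchor *closest to the original TSS* — i.e. the most downstream
  positive anchor — so corrected 5' ends typically land one scan step
  upstream of the assembled TSS rather than at the true TSS when the
  truncation exceeds ~300 bp.  In the default recovery experiment roughly
  half of corrected ends land within one scan step of the truth, although
  the median distance to the nearest CAGE peak always improves and the SVM
  decision score itself peaks at the aligned window.  A highest-score
  selection rule would essentially eliminate the bias, but the closest-region
  rule is the published procedure and is what this package implements.
- Scan windows are featurized in plus orientation; strongly
  strand-asymmetric promoter sequence signals would be diluted.
- The exact-p PWM scan assumes a 0-order background; CpG-rich backgrounds
  inflate GC-rich motif hits (mitigated here by the presence threshold).
- GSEA significance is positive-side only by default; anti-correlated
  associations need the exposed negative-side option.
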