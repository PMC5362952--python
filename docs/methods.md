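# Methods

`armloy` detects chromosome-arm aneuploidy — in particular mosaic and
somatic loss of chromosome Y (LOY) and X (LOX) — from binned
whole-genome read coverage, validates LOY with a chrY PCR-probe panel,
and runs the standard downstream association statistics. A seeded
synthetic-cohort generator provides planted ground truth so that every
stage is testable without external data.

## Coverage model and normalization

Read counts are taken in fixed 5 kb bins tiling each chromosome
(0-based half-open; trailing partial bins dropped). For each sample,
every bin count is divided by the sample's **median autosomal bin
count**. This makes the signal depth-free: a diploid autosomal bin sits
at 1.0, a single-copy sex chromosome in males at 0.5, and chrY is
absent (no baseline) in females. Normalization is scale-invariant by
construction — multiplying a sample's counts by any constant leaves
the normalized vector unchanged.

Arm units are the p and q arms split at the centromere; chromosome Y is
always one unit, because it is lost as a whole and arm-level resolution
would only dilute the signal. A bin straddling the centromere belongs
to the q arm (assignment by bin end).

## Stable-bin selection

Mappability and other static artefacts bias some bins in every sample.
Within each arm, bins are ranked by the **median across normal
samples** of |normalized coverage − baseline|, where the baseline is
the sex-aware expected dosage (1.0 autosomes; 0.5 male X/Y; 1.0 female
X). Only the K = 1000 most stable bins per arm are retained (all bins
when the arm has fewer); ties are broken by genomic position, leftmost
first. Bins with zero coverage in at least half the usable normals are
excluded before ranking, guarding division artefacts. Divergence is
measured per arm rather than genome-wide so that each tested unit keeps
its own well-behaved support.

Each sample × arm is then summarized by the **median normalized
coverage over the selected bins** — the single statistic on which
aneuploidy is tested.

## Mixture null and calling

Across a cohort, an arm's medians form a tight mode at the expected
dosage plus, when an aberration recurs, a displaced mode from affected
samples. A two-component univariate Gaussian mixture is fitted by EM:

* deterministic 2-means initialization (centers at the quartiles);
* convergence when the log-likelihood moves < 1e-8, at most 500
  iterations;
* component sd floored at max(1e-4, 0.05 × sd of the input). The
  relative part matters: at λ ≈ 30 reads/bin the arm medians are
  quantized to steps of ~1/60, and without a resolution-scale floor a
  component collapses onto an exact-tie atom and sheds its near
  neighbours, corrupting the weights;
* **model selection by BIC** against a single Gaussian — the extra
  component is kept only if it pays for its three extra parameters.
  On unimodal data an unconstrained two-component fit splits the sample
  and understates the null spread;
* fewer than 8 values (or no spread): single-Gaussian fallback with a
  warning.

The **null is the heavier component**. When the weights are nearly tied
(within 0.15) the component whose mean is nearer the expected baseline
is the null instead: with an aberration in close to half the cohort the
weight ordering is decided by noise, while the unaffected mode is
always the one at the expected dosage. This matters for near-ubiquitous
events such as 3p loss in clear cell renal cell carcinoma (~90% of
tumors): fitting across tumors *and* matched normals jointly (the
default; sex chromosomes are fitted per sex since baselines differ)
keeps the unaffected mode in the majority, and the near-tie rule
absorbs the residual ambiguity. A per-tissue-class fit is available
(`pool_tissues=False`), but with a majority aberration it would hand
the null to the affected mode.

Each sample's arm median gets a two-sided normal tail p-value under the
null, Bonferroni-adjusted with m = (arm units tested for the sample's
sex) × (samples in its tissue class) — the multiplicity actually
incurred; m is configurable. A call is flagged when adjusted p < 0.01
**and** the estimated affected-cell fraction is at least 0.10.

## Cell-fraction estimate

Linear dosage mixing: a fraction f of affected cells changes expected
coverage by 0.5·f per copy changed, so

* single-copy units (baseline 0.5): loss f = (0.5 − cov)/0.5, gain
  f = (cov − 0.5)/0.5;
* two-copy units (baseline 1.0), one copy changed: loss
  f = (1 − cov)/0.5, gain f = (cov − 1)/0.5;

clipped to [0, 1]. E.g. chrY coverage 0.125 implies 75% of cells with
LOY. The direction is taken from the sign of (coverage − null mean).

## PCR-probe caller

The probe panel (20 chrY loci by default) mirrors the coverage
pipeline: each probe is normalized by its median across the designated
normal samples, each sample summarized by its median normalized
amplification, and the mixture null fitted **on normals only** (the
panel has no per-arm structure, and tumor summaries are exactly what is
under test). An intact Y sits at 1.0 after normalization, so the
fraction is 1 − summary. Flag rule: p < 0.01 and fraction strictly
\> 0.10, with no multiplicity adjustment — one summary per sample is
tested. Per-locus tumor/normal ratios provide the whole-chromosome
depletion view.

## Association statistics

* **Differential expression**: Student's (pooled-variance) t-test per
  gene on log2(RPKM + 1) between carrier and non-carrier tumors
  (pseudocount configurable; Welch behind a flag), Benjamini–Hochberg
  over all tested genes, significant at FDR < 0.01. Genes with zero
  variance in both groups get p = 1.
* **Expression vs fraction**: per-gene OLS of expression on the
  affected-cell fraction, two-sided slope p.
* **Mosaic LOY vs age**: maximum-likelihood logistic regression of the
  blood flag on age; Wald p and per-year odds ratio; complete
  separation is reported, not raised.
* **Co-occurrence**: two-sided Fisher exact test (probability-mass
  rule) on 2×2 tables; a zero margin gives p = 1.
* **Aberration union**: per sex group, samples with any of a set of
  boolean aberration flags, with integer-rounded percentage.

## Synthetic cohorts

The generator emulates the study conditions end to end.

* **Genome**: human-like karyotype (GRCh37 lengths and centromeres) at
  1/10 linear scale with the same 5 kb bins, giving ~260–3,000 bins per
  arm and ~1,200 on chrY — normalization is scale-free, so the smaller
  genome changes nothing but runtime (full 93-patient cohorts run in
  seconds). Arbitrary karyotypes are configurable.
* **Counts**: count(s, b) ~ Poisson(λ · bias_b · dosage), λ = 30
  reads/bin by default (sequencing depth is a free parameter of the
  model; 30 gives arm-median noise small against the 10% fraction
  threshold). The per-bin bias is lognormal (σ = 0.1), drawn once per
  cohort and shared by all samples — a static mappability-style
  artefact that makes the stable-bin filter necessary; there is no GC
  or positional autocorrelation model. Dosage factors: loss of the only
  copy 1 − f; loss of one of two 1 − f/2; gains 1 + f and 1 + f/2
  respectively (each mirrors the caller's fraction formula exactly).
* **Events** are planted with exact carrier counts (never binomial
  draws) and fractions drawn uniformly from a stated range or given
  explicitly; only karyotype validity is enforced (chrY events require
  males). Whole-chromosome events (`chrX`, `chrY`) apply to every bin
  of the chromosome.
* **Ages**: non-carriers ~ N(59, 8); patients with blood LOY
  ~ N(69, 8) — the mosaic-LOY age skew; configurable.
* **Expression**: Y-linked gene means scale by (1 − f); multiplicative
  lognormal noise with sd 0.3 on the log2 scale; Y genes in females at
  a noise floor. Default annotation: 11 expressed chrY genes (base
  8–64 RPKM) + 1,000 autosomal background genes (lognormal base).
* **Probes**: value = probe efficiency × Y dosage × lognormal noise
  (sd 0.1 log2); a female control sits at the detection floor.

All randomness descends from a single cohort seed; identical
(config, seed) reproduce byte-identical outputs.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: overdispersed and
GC/position-correlated coverage noise, replication-timing waves,
subclonal mixtures and copy-neutral LOH, tumor purity varying by
region, batch structure in expression, and semi-quantitative PCR
saturation. The planted effects are clean single events on an otherwise
diploid background, so recovery rates here are upper bounds.

## Numerical choices and degenerate inputs

Medians of even-length sets are the mean of the two central values.
A sample whose autosomal median count is zero is rejected as unusable.
Arms with no usable normals (e.g. chrY in an all-female cohort) are
dropped with a warning. Constant mixture inputs yield a degenerate
single-Gaussian null (σ at the floor) under which every sample gets
p = 1. Coverage quantization at λ = 30 limits single-sample fraction
estimates to steps of ~0.07 at high f; across flagged calls the mean
absolute error against planted fractions stays below 0.05.

## Known limitations

The Bonferroni denominator (arms × samples per tissue class) is one
defensible choice among several; it is exposed as a parameter. The
near-tie baseline rule would mis-assign the null in the (unobserved)
scenario of an aberration in just under half the cohort whose displaced
mode lands nearer the baseline than the unaffected mode. Focal/sub-arm
events are out of scope: the caller tests whole arm units only, and
focal-deletion evidence enters only as boolean sample-sheet flags.
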