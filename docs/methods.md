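# Methods

This note records the statistical model, the choices made where the
design was genuinely open, and what the synthetic benchmark does and
does not demonstrate.

## Data model and normalization

The unit of analysis is a genes × samples matrix of log2 intensities
with a sample → condition design. Quantile normalization maps each
sample onto the mean of the per-sample sorted vectors. Ties within a
sample are resolved with average ranks and linear interpolation into
the reference distribution, so a pair of tied values receives the mean
of the two reference values at their rank positions; this makes the
transform deterministic and idempotent (verified to 1e-9). Quantile
normalization assumes most genes are unchanged between samples; see
*Limitations* for what happens when that fails.

## Expression gating

Pooled per-gene-per-sample log2 intensities are modeled as a
two-component Gaussian mixture (unexpressed background, expressed
signal) fitted by EM:

- initialization: means at the 25th/75th percentiles, equal weights,
  both sds at half the pooled sd;
- convergence: relative log-likelihood change ≤ 1e-6, at most 500
  iterations; the log-likelihood trace is retained and checked to be
  non-decreasing;
- degeneracy: any component sd falling below 1e-3 raises a
  collapsed-component error rather than returning a meaningless gate;
- the gate is the intensity strictly between the two means where the
  weighted component densities are equal (posterior 0.5), found by a
  bracketing root search on a dense grid (robust to unequal weights).

The mixture is fitted on pooled intensities rather than per-gene
summaries because the gate is applied per sample: a gene is "expressed"
if it exceeds the threshold in at least one sample (strictly). The
threshold is always data-derived; pipeline and CLI accept an override
to reproduce a previously published gate. Thresholds are reported to
four decimal places in manifests, the customary reporting precision
for such gates.

## The integrative test

With two replicates per group, gene-wise parametric inference is
uninformative, so the caller combines two weak signals and calibrates
them globally:

- pooled-variance two-sample *t* (df = n₁+n₂−2). Welch's correction is
  deliberately not used: its df estimate is degenerate at n = 2, and
  the permutation calibration absorbs variance misspecification. Rows
  with zero pooled variance return t = 0, p = 1 when the means agree
  and a signed-infinity sentinel otherwise (the permutation path then
  provides the usable p).
- log2 median difference. Note that with duplicates the median equals
  the mean, so this statistic coincides with the mean-based log2FC at
  n = 2; it differs for ≥3 replicates, and it is retained as a separate
  column and test because the two statistics are distinct quantities in
  the calling rule.
- combination: Stouffer's z on (p_t, p_md), inputs clamped to
  [1e-15, 1−1e-15]. Fisher's method is available behind a switch; its
  combined p is mapped back to a normal z so ranking is
  method-agnostic.

**Permutation null.** Balanced relabelings only: each permuted group
keeps its size. Relabelings are enumerated as *unordered* sample
partitions with the identity partition excluded — for a 2v2 design that
is C(3,1) − 1 = 2 distinct relabelings (complementary assignments carry
identical two-sided information, and the identity's contribution is
supplied by add-one smoothing). When a larger design admits more
relabelings than requested, a seeded random subset is drawn. Because a
gene-wise null from 2 relabelings is hopeless, permuted statistics are
pooled across genes × relabelings; the attainable p resolution is
1/(G·P+1). Permuted statistics are pushed through the same combination
path against the same pooled null, and the adjusted p-value is the
one-sided empirical tail probability of the observed combined z with
add-one smoothing (guaranteeing p ∈ (0, 1]). Benjamini–Hochberg q of
the adjusted p is reported as an extra column but never used in the
calling rule.

**Calling rule.** DEG iff adjusted p < α (default 0.05) and |log2FC|
strictly exceeds the fold-change cutoff, defined as the 95% quantile
(linear interpolation) of pooled |permuted log2FC|. Both inequalities
are strict. This rule controls a *per-gene false call rate*, not the
false discovery rate: under the null roughly 3% of genes pass the
joint rule (the two filters are strongly correlated), so the realized
FDP depends on the true signal density.

## Comparison and enrichment

Two DEG sets over the same universe partition their union into seven
direction patterns; the discordant pattern covers both orientations.
The overlap test is a one-sided (enrichment) Fisher's exact test whose
universe is the expressed-gene set — the population actually tested —
with the sample odds ratio (n11·n00)/(n10·n01) and an infinity sentinel
for empty denominator cells. Dependency fractions default to the union
denominator ("of the genes affected by either perturbation, how many by
only one / by both"); the full-universe denominator is available as a
mode. Enrichment is a plain hypergeometric upper tail per GMT term
(equivalent to one-sided Fisher, verified to 1e-12), with universe =
expressed genes ∩ genes present in the collection, raw p for the
p < 0.05 & hits > 2 reporting filter, and BH q as an extra column.

## qPCR

2^−ΔΔCt with technical replicates averaged on the Ct scale (ΔΔCt is
defined on cycle numbers) and the control ΔCt taken as the mean over
control samples. Amplification efficiency is fixed at 2; no
efficiency-corrected variant is in scope.

## Synthetic-data generator

The generator emulates the statistical structure of a duplicate-array
knockdown study on the post-log2 scale: per-gene baselines from
w·N(μ_e, σ_e²) + (1−w)·N(μ_u, σ_u²) (defaults 0.5, N(8, 1²) expressed,
N(3, 0.5²) unexpressed — well-separated components typical of
two-population intensity histograms), i.i.d. replicate noise
N(0, 0.25), and additive spiked effects on the log2 scale arranged in
the seven direction patterns across two knockdown groups. Defaults:
2,000 genes, 60 spiked genes per pattern at 2.0 log2 units, i.e. about
30% of the expressed universe regulated per contrast. The spike density
was fixed by a pilot operating-characteristics simulation: because the
caller controls a per-gene false call rate (~3%), a benchmark that asks
for FDP ≤ 0.1 is only meaningful when true positives outnumber that
base rate roughly ten to one, which a strong knockdown plausibly
produces. Spiked genes are always drawn from the expressed component.
All randomness flows from a single explicitly seeded generator per
call; equal seeds give byte-identical output.

What the generator does **not** model: probe-level artifacts, batch or
technical between-sample distribution shifts, intensity-dependent
variance, correlated genes. Consequently a passing benchmark
demonstrates the correctness and calibration of the statistical
machinery, not robustness to real-array technical structure.

## Benchmark protocols and problem sizes

- *Null calibration*: 10,000 genes, two conditions × 2 replicates,
  full pipeline (quantile normalization → mixture gate → permutation
  test); the fraction of tested genes called is ≈3% and the adjusted
  p-values are near-uniform (KS < 0.02 on ~5,000 tested genes).
- *Cutoff semantics*: ≥10⁵ pooled null values (50,000 genes × 2
  relabelings); the empirical CDF of |permuted log2FC| at the cutoff is
  0.95 within half a point.
- *Spike recovery*: 10 seeds of the default spike design, evaluated on
  the gated simulator output **without** quantile normalization.
  Rationale: the generator draws all samples on a common scale, so QN
  has nothing to remove there, and with ~30% genes truly shifted QN's
  mostly-unchanged assumption is violated — it then *injects*
  between-group distortion (null fold-change sd inflates from 0.25 to
  ~0.49) that is a property of the normalization/benchmark mismatch,
  not of the caller under test. Measured: sensitivity 1.00, FDP 0.085,
  cluster agreement 0.979.

## Limitations

- Quantile normalization degrades when a large asymmetric fraction of
  genes is truly differential; on real data with strong global effects
  a different normalization should be considered upstream.
- The pooled permutation null assumes genes are exchangeable under
  relabeling; strongly heteroskedastic genes violate this and inherit a
  shared calibration.
- With duplicates the median-difference statistic is redundant with the
  mean fold change; it only adds information for ≥3 replicates.
- The adjusted p resolution is bounded by 1/(G·P+1); tiny matrices give
  coarse p-value grids.
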