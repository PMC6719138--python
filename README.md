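# permdeg

Differential expression for transcriptome experiments with *very* small
replicate counts — the duplicate-array regime where parametric testing
alone cannot be trusted — plus the comparative machinery needed when two
perturbations (for example two gene knockdowns) are contrasted against
the same wild-type reference.

The package is aimed at analysts working with legacy microarray or
small pilot expression studies, and at methodologists who want a
fully-tested, ground-truth-instrumented implementation of this class of
pipeline: every stage can be exercised end to end on a built-in
synthetic-data generator with known spiked effects.

## The method

Given a genes × samples matrix of log2 intensities and a sample → group
design:

1. **Quantile normalization** forces every sample onto the mean of the
   per-sample sorted vectors, preserving within-sample ranks (tied
   values receive the mean reference value of their rank positions).
2. **Expression gating.** A two-component Gaussian mixture is fitted by
   EM to the pooled log2 intensities; the equal-density crossing
   between the component means (where the posterior is 0.5) separates
   unexpressed background from expressed signal. Genes above the
   threshold in at least one sample form the tested universe.
3. **Integrative permutation test.** For each gene and contrast
   (test group vs reference) two statistics are computed: the
   pooled-variance two-sample *t* and the log2 median difference
   Δmed = median(test) − median(ref). Their p-values (parametric for
   *t*; empirical for Δmed) are combined with Stouffer's method,
   z = (z_t + z_md)/√2. The null is built by balanced relabeling of
   the contrast's samples (exhaustive for duplicate designs) with the
   permuted statistics pooled across all genes, and the **adjusted
   p-value** is the add-one-smoothed empirical tail probability of the
   combined z in that pooled null.
4. **Data-driven fold-change cutoff.** The 95% quantile of the pooled
   |permuted log2FC| serves as the fold-change threshold; a gene is a
   DEG iff adjusted p < 0.05 **and** |log2FC| exceeds the cutoff (both
   strict).
5. **Comparison of two contrasts.** Genes differential in at least one
   contrast are partitioned into seven direction patterns (common up,
   unique up ×2, discordant, unique down ×2, common down); overlap
   significance is a one-sided Fisher's exact test over the expressed
   universe, and "dependent on either / on both" fractions are
   reported.
6. **Enrichment.** Hypergeometric over-representation of any gene list
   against GMT gene sets, keeping terms with p < 0.05 and more than two
   query hits.
7. **qPCR quantification.** 2^−ΔΔCt relative expression with
   ΔCt = Ct(target) − Ct(reference gene) and
   ΔΔCt = ΔCt(sample) − ΔCt(control mean).

## Worked example

`examples/01_simulate_and_call_degs.py` simulates the default study
conditions (2,000 genes, WT/KD1/KD2 in duplicate, 60 spiked genes per
direction pattern at 2.0 log2 units, replicate noise 0.25) and calls
DEGs for KD1 vs WT:

```
simulated 2000 genes x 6 samples
expression gate 4.5999 -> 1011 expressed genes
fold-change cutoff 0.5029 (95% of |permuted log2FC|, exhaustive:2 relabelings)
329 DEGs at adjusted p < 0.05 and |log2FC| > cutoff
sensitivity 1.000, false-discovery proportion 0.088 against the spiked ground truth
```

The gate (≈4.60 here) and the cutoff (≈0.50) are *derived from the
data*, not fixed constants: the gate is where the unexpressed and
expressed mixture densities cross, and the cutoff is the 95th
percentile of fold changes seen under sample relabeling — so 95% of
null fold changes fall below it by construction. The other examples
cover gating (`02`), the seven-pattern comparison with Venn counts and
the overlap test (`03`), GMT enrichment (`04`) and ΔΔCt quantification
(`05`); each prints its results with a line of interpretation.

A thin CLI mirrors the library (`permdeg simulate|normalize|deg|
compare|enrich|qpcr|run`); `permdeg run` executes the whole pipeline
and writes per-stage TSV/JSON artifacts plus a manifest with every
seed and derived threshold needed to re-run bit-identically.

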