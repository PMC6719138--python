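"""Compare two knockdown DEG sets: pattern clusters, Venn, overlap test.

Both knockdowns are contrasted against the same wild-type reference;
genes differential in at least one contrast fall into seven direction
patterns (unique up/down, common up/down, discordant).
"""

from permdeg import (
    CLUSTER_LABELS,
    Contrast,
    SimConfig,
    assign_clusters,
    dependency_fractions,
    fit_expression_gmm,
    overlap_fisher,
    select_expressed,
    simulate_matrix,
    test_contrast,
    venn_counts,
)

matrix, truth = simulate_matrix(SimConfig(seed=3))
fit = fit_expression_gmm(matrix.values.to_numpy().ravel(), seed=3)
expressed = select_expressed(matrix, fit.threshold)

deg1 = test_contrast(expressed, Contrast("KD1", "WT"), seed=3).deg_set
deg2 = test_contrast(expressed, Contrast("KD2", "WT"), seed=3).deg_set
print(f"KD1 vs WT: {len(deg1)} DEGs; KD2 vs WT: {len(deg2)} DEGs")

clusters = assign_clusters(deg1, deg2)
for cid, count in clusters.counts().items():
    print(f"  cluster {cid} ({CLUSTER_LABELS[cid]:<24s}): {count:4d} genes")

only_a, only_b, both = venn_counts(deg1, deg2)
print(f"Venn: {only_a} only KD1, {only_b} only KD2, {both} shared")

overlap = overlap_fisher(deg1, deg2, expressed.n_genes)
print(f"overlap significance (one-sided Fisher): p = {overlap.p_value:.3g}, "
      f"odds ratio {overlap.odds_ratio:.2f}")

either, shared = dependency_fractions(deg1, deg2, expressed.n_genes)
print(f"of the union, {either:.0%} depend on only one knockdown "
      f"and {shared:.0%} on both")
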