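"""Gene-set over-representation of a DEG cluster against a GMT collection.

A small synthetic GMT collection is built on the fly: one set holding
spiked genes (truly enriched among DEGs) and two background sets.  Each
term is scored with the hypergeometric tail; terms with p < 0.05 and
more than two query hits are reported.
"""

import tempfile
from pathlib import Path

from permdeg import (
    Contrast,
    SimConfig,
    filter_terms,
    fit_expression_gmm,
    hypergeom_enrich,
    read_gmt,
    select_expressed,
    simulate_matrix,
    test_contrast,
)

matrix, truth = simulate_matrix(SimConfig(seed=4))
fit = fit_expression_gmm(matrix.values.to_numpy().ravel(), seed=4)
expressed = select_expressed(matrix, fit.threshold)
degs = test_contrast(expressed, Contrast("KD1", "WT"), seed=4).deg_set

spiked = list(truth.table.index[truth.table.pattern_id > 0])
background = list(truth.table.index[truth.table.is_expressed])
gmt_text = "\n".join([
    "SPIKED\tsimulated effect genes\t" + "\t".join(spiked),
    "BG_A\tfirst background slice\t" + "\t".join(background[:150]),
    "BG_B\tsecond background slice\t" + "\t".join(background[150:300]),
]) + "\n"

with tempfile.TemporaryDirectory() as tmp:
    gmt_path = Path(tmp) / "sets.gmt"
    gmt_path.write_text(gmt_text, encoding="utf-8")
    collection = read_gmt(gmt_path)

universe = set(expressed.gene_ids) & collection.all_genes()
query = degs.gene_set() & universe
records = hypergeom_enrich(query, collection, universe)
print(f"query: {len(query)} DEGs over a universe of {len(universe)} genes")
for r in records:
    print(f"  {r.term_id:<8s} k={r.k:3d} K={r.K:3d} "
          f"fold={r.fold_enrichment:5.2f}  p={r.p_value:.3g}")
kept = filter_terms(records)
print(f"{len(kept)} term(s) pass p < 0.05 with more than 2 query genes")
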