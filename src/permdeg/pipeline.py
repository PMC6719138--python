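"""End-to-end orchestration: normalize, gate, test, compare, enrich.

The stage order follows the analysis the package implements: (optional)
log2 transform, quantile normalization, mixture-model expression gating,
the permutation-combined differential test per knockdown contrast, the
seven-pattern comparison of the two DEG sets, and gene-set enrichment
per pattern cluster.  Every run writes a JSON manifest with the seeds
and derived thresholds needed to re-run bit-identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import io as pio
from .compare import assign_clusters, dependency_fractions, overlap_fisher, venn_counts
from .degtest import Contrast, DegResult, test_contrast
from .enrichment import hypergeom_enrich, read_gmt, records_to_frame
from .matrix import ExpressionMatrix, PermdegError
from .preprocess import (
    GmmFit,
    fit_expression_gmm,
    log2_transform,
    quantile_normalize,
    select_expressed,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("permdeg")


@dataclass
class PipelineConfig:
    """Settings for :func:`run_pipeline`.

    Defaults reproduce the conventional calling rule: significance at
    adjusted p < 0.05 and a fold-change cutoff at the 95% quantile of
    the permutation null.
    """

    matrix_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    outdir: str = "permdeg_out"
    alpha: float = 0.05
    fc_quantile: float = 0.95
    n_permutations: int = 1000
    seed: int = 0
    gmm_seed: int = 0
    expression_threshold_override: float | None = None
    combination_method: str = "stouffer"
    fisher_sidedness: str = "greater"
    denominator_mode: str = "union"
    reference_group: str | None = None
    log2_input: bool = False
    gate_before_normalize: bool = False
    force: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise PermdegError("alpha must lie in (0, 1)")
        if not 0.0 < self.fc_quantile < 1.0:
            raise PermdegError("fc_quantile must lie in (0, 1)")


@dataclass
class PipelineResult:
    normalized: ExpressionMatrix
    gmm: GmmFit | None
    threshold: float
    expressed: ExpressionMatrix
    deg_results: dict[str, DegResult]
    comparison: dict | None
    enrichment: dict | None
    manifest: dict = field(default_factory=dict)


def _prepare_outdir(outdir: Path, force: bool) -> None:
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise PermdegError(
            f"output directory {outdir} is not empty; pass force=True to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)


def run_pipeline(
    config: PipelineConfig, matrix: ExpressionMatrix | None = None
) -> PipelineResult:
    """Run every stage and write all artifacts under ``config.outdir``.

    ``matrix`` may be passed directly (e.g. fresh from the simulator);
    otherwise it is read from ``config.matrix_path``/``design_path``.
    """
    outdir = Path(config.outdir)
    _prepare_outdir(outdir, config.force)

    if matrix is None:
        if config.matrix_path is None:
            raise PermdegError("either a matrix or matrix_path is required")
        logger.info("[load] reading %s", config.matrix_path)
        matrix = pio.read_expression_tsv(config.matrix_path, config.design_path)

    if config.log2_input:
        logger.info("[log2] transforming raw intensities")
        matrix = log2_transform(matrix)

    def gate(m: ExpressionMatrix) -> tuple[GmmFit | None, float, ExpressionMatrix]:
        if config.expression_threshold_override is not None:
            thr = float(config.expression_threshold_override)
            logger.info("[gate] using threshold override %.4f", thr)
            return None, thr, select_expressed(m, thr)
        fit = fit_expression_gmm(m.values.to_numpy().ravel(), seed=config.gmm_seed)
        logger.info(
            "[gate] mixture threshold %.4f (converged=%s, %d iterations)",
            fit.threshold, fit.converged, fit.n_iter,
        )
        return fit, fit.threshold, select_expressed(m, fit.threshold)

    if config.gate_before_normalize:
        gmm, threshold, matrix = gate(matrix)
        logger.info("[normalize] quantile-normalizing %d genes", matrix.n_genes)
        normalized = quantile_normalize(matrix)
        expressed = normalized
    else:
        logger.info("[normalize] quantile-normalizing %d genes", matrix.n_genes)
        normalized = quantile_normalize(matrix)
        gmm, threshold, expressed = gate(normalized)
    logger.info("[gate] %d of %d genes expressed", expressed.n_genes, normalized.n_genes)

    pio.write_expression_tsv(normalized, outdir / "normalized.tsv")
    pio.write_design_tsv(normalized, outdir / "design.tsv")
    if gmm is not None:
        pio.write_gmm_json(gmm, outdir / "gmm_fit.json")

    groups = expressed.groups()
    reference = config.reference_group or groups[0]
    if reference not in groups:
        raise PermdegError(f"reference group {reference!r} not in design")
    contrasts = [Contrast(g, reference) for g in groups if g != reference]
    if not contrasts:
        raise PermdegError("design has no non-reference group to test")

    deg_results: dict[str, DegResult] = {}
    for contrast in contrasts:
        logger.info("[deg] testing %s", contrast)
        result = test_contrast(
            expressed,
            contrast,
            n_permutations=config.n_permutations,
            seed=config.seed,
            alpha=config.alpha,
            fc_quantile=config.fc_quantile,
            combination=config.combination_method,
        )
        deg_results[str(contrast)] = result
        logger.info(
            "[deg] %s: cutoff %.4f, %d DEGs", contrast, result.fc_cutoff,
            len(result.deg_set),
        )
        result.stats.to_csv(outdir / f"deg_{contrast}.tsv", sep="\t")
        pio.write_json(
            {
                "contrast": str(contrast),
                "alpha": config.alpha,
                "fc_cutoff": result.fc_cutoff,
                "fc_cutoff_4dp": f"{result.fc_cutoff:.4f}",
                "fc_quantile": config.fc_quantile,
                "n_permutations": result.null.n_permutations,
                "scheme": result.null.scheme,
                "seed": config.seed,
                "n_degs": len(result.deg_set),
            },
            outdir / f"deg_{contrast}.json",
        )

    comparison = None
    enrichment_out = None
    if len(contrasts) == 2:
        res_a = deg_results[str(contrasts[0])]
        res_b = deg_results[str(contrasts[1])]
        clusters = assign_clusters(res_a.deg_set, res_b.deg_set)
        only_a, only_b, both = venn_counts(res_a.deg_set, res_b.deg_set)
        overlap = overlap_fisher(res_a.deg_set, res_b.deg_set, expressed.n_genes)
        either, both_frac = dependency_fractions(
            res_a.deg_set, res_b.deg_set, expressed.n_genes, config.denominator_mode
        )
        comparison = {
            "clusters": clusters,
            "cluster_counts": clusters.counts(),
            "venn": {"only_a": only_a, "only_b": only_b, "both": both},
            "overlap": overlap,
            "dependency_fractions": {
                "either_not_both": either,
                "both": both_frac,
                "denominator_mode": config.denominator_mode,
            },
        }
        logger.info(
            "[compare] venn (%d, %d, %d); overlap p=%.3g", only_a, only_b, both,
            overlap.p_value,
        )
        with open(outdir / "clusters.tsv", "w", encoding="utf-8") as fh:
            fh.write("gene_id\tcluster_id\tdirection_a\tdirection_b\n")
            for gene in sorted(clusters.clusters):
                fh.write(
                    f"{gene}\t{clusters.clusters[gene]}\t"
                    f"{res_a.deg_set.genes.get(gene, '')}\t"
                    f"{res_b.deg_set.genes.get(gene, '')}\n"
                )
        pio.write_json(
            {"only_a": only_a, "only_b": only_b, "both": both}, outdir / "venn.json"
        )
        pio.write_json(
            {
                "table": [list(r) for r in overlap.table],
                "odds_ratio": overlap.odds_ratio,
                "p_value": overlap.p_value,
                "sidedness": overlap.sidedness,
                "dependency_fractions": comparison["dependency_fractions"],
            },
            outdir / "overlap.json",
        )

        if config.gmt_path:
            collection = read_gmt(config.gmt_path)
            universe = set(expressed.gene_ids) & collection.all_genes()
            enrichment_out = {}
            for cluster_id in range(1, 8):
                query = clusters.genes_in(cluster_id) & universe
                if not query or not universe:
                    continue
                records = hypergeom_enrich(query, collection, universe)
                frame = records_to_frame(records)
                frame.to_csv(
                    outdir / f"enrichment_cluster{cluster_id}.tsv", sep="\t", index=False
                )
                enrichment_out[cluster_id] = records
            logger.info("[enrich] tested %d clusters", len(enrichment_out))

    manifest = {
        "package": "permdeg",
        "config": {
            k: v for k, v in asdict(config).items() if not k.startswith("_")
        },
        "reference_group": reference,
        "contrasts": [str(c) for c in contrasts],
        "n_genes_input": matrix.n_genes,
        "n_genes_expressed": expressed.n_genes,
        "expression_threshold": threshold,
        "expression_threshold_4dp": f"{threshold:.4f}",
        "fc_cutoffs": {
            name: res.fc_cutoff for name, res in deg_results.items()
        },
        "deg_counts": {name: len(res.deg_set) for name, res in deg_results.items()},
        "versions": _versions(),
    }
    pio.write_json(manifest, outdir / "manifest.json")
    return PipelineResult(
        normalized=normalized,
        gmm=gmm,
        threshold=threshold,
        expressed=expressed,
        deg_results=deg_results,
        comparison=comparison,
        enrichment=enrichment_out,
        manifest=manifest,
    )


def _versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy

    from . import __version__

    return {
        "permdeg": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
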