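"""Permutation-calibrated differential expression for tiny replicate counts.

With only two arrays per condition a parametric test alone is hopeless,
so significance is calibrated empirically: for every gene a pooled
two-sample t statistic and a log2 median-difference statistic are
combined (Stouffer's z by default) and referred to a null distribution
built by relabeling samples between the two groups of the contrast and
pooling the permuted statistics across all genes.  The same permutation
null supplies a data-driven fold-change cutoff: the chosen quantile
(default 95%) of the absolute permuted log2 fold changes.  A gene is
called differentially expressed when its permutation-adjusted p-value is
below ``alpha`` AND its absolute log2 fold change exceeds the cutoff,
both strictly.

Relabelings are balanced (each permuted group keeps its size) and
enumerated as unordered sample partitions with the identity partition
excluded; a 2-vs-2 contrast therefore has exactly 2 distinct
relabelings, and the null has size ``n_genes * n_relabelings``.  When
the design admits more relabelings than requested, a seeded random
subset is used instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix, PermdegError

__all__ = [
    "Contrast",
    "NullDistributions",
    "DegSet",
    "DegResult",
    "t_statistic",
    "median_difference",
    "balanced_relabelings",
    "build_null",
    "empirical_p",
    "combine_pvalues",
    "adjusted_pvalues",
    "fc_cutoff",
    "call_degs",
    "test_contrast",
]

_P_CLAMP = 1e-15
_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class Contrast:
    """A two-group comparison: ``test_group`` versus ``reference_group``."""

    test_group: str
    reference_group: str

    def __post_init__(self) -> None:
        if self.test_group == self.reference_group:
            raise PermdegError("contrast groups must be distinct")

    def __str__(self) -> str:  # used in file names and manifests
        return f"{self.test_group}_vs_{self.reference_group}"


@dataclass
class NullDistributions:
    """Pooled permutation null statistics for one contrast.

    Each array has length ``n_genes * n_permutations`` (gene-major).
    ``null_combined_z`` holds the permuted statistics pushed through the
    same p-value combination path used for the observed genes, against
    this very null.
    """

    null_t: np.ndarray
    null_md: np.ndarray
    null_log2fc: np.ndarray
    null_combined_z: np.ndarray
    n_permutations: int
    scheme: str
    df: int


@dataclass
class DegSet:
    """Genes called differentially expressed for one contrast."""

    contrast: Contrast
    alpha: float
    fc_cutoff: float
    genes: dict[str, str]  # gene_id -> "up" | "down"
    universe: frozenset = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def gene_set(self) -> set[str]:
        return set(self.genes)

    def upregulated(self) -> set[str]:
        return {g for g, d in self.genes.items() if d == "up"}

    def downregulated(self) -> set[str]:
        return {g for g, d in self.genes.items() if d == "down"}


@dataclass
class DegResult:
    """Full output of :func:`test_contrast`."""

    contrast: Contrast
    stats: pd.DataFrame
    null: NullDistributions
    fc_cutoff: float
    deg_set: DegSet


# ---------------------------------------------------------------------------
# elementary statistics


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized pooled-variance two-sample t over rows of ``a`` and ``b``.

    Rows with zero pooled variance get t=0, p=1 when the means agree and
    a signed infinity sentinel with p=0 otherwise (the permutation path
    then supplies the usable p-value).
    """
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise PermdegError("t statistic needs >=2 values per group")
    df = na + nb - 2
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    ssa = ((a - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((b - mb[:, None]) ** 2).sum(axis=1)
    se = np.sqrt((ssa + ssb) / df * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    zero_se = se == 0
    if zero_se.any():
        sentinel = np.copysign(np.inf, diff[zero_se])
        sentinel[diff[zero_se] == 0] = 0.0
        t = t.copy()
        t[zero_se] = sentinel
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(zero_se & (diff == 0), 1.0, p)
    return t, p, df


def t_statistic(group_a, group_b) -> tuple[float, float]:
    """Pooled-variance two-sample t with a two-tailed p (df = n_a+n_b-2)."""
    a = np.asarray(group_a, dtype=float)[None, :]
    b = np.asarray(group_b, dtype=float)[None, :]
    t, p, _ = _pooled_t(a, b)
    return float(t[0]), float(p[0])


def median_difference(group_a, group_b) -> float:
    """median(group_a) - median(group_b), on log2 intensities."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise PermdegError("median difference needs non-empty groups")
    return float(np.median(a) - np.median(b))


def _row_stats(a: np.ndarray, b: np.ndarray):
    """(t, p_t, median_diff, log2fc) for each row; log2fc is mean-based."""
    t, p_t, _ = _pooled_t(a, b)
    md = np.median(a, axis=1) - np.median(b, axis=1)
    fc = a.mean(axis=1) - b.mean(axis=1)
    return t, p_t, md, fc


# ---------------------------------------------------------------------------
# permutation machinery


def balanced_relabelings(n_test: int, n_ref: int) -> list[tuple[int, ...]]:
    """Distinct balanced relabelings of ``n_test + n_ref`` sample slots.

    Each relabeling is the tuple of slot indices assigned to the test
    group (slots 0..n_test-1 hold the original test samples).  The
    identity partition is excluded.  For equal group sizes a partition
    and its complement carry the same two-sided information, so only one
    canonical representative (the side containing slot 0) is kept:
    a 2v2 design yields C(3,1) - 1 = 2 relabelings.
    """
    n = n_test + n_ref
    identity = tuple(range(n_test))
    out: list[tuple[int, ...]] = []
    if n_test == n_ref:
        for rest in combinations(range(1, n), n_test - 1):
            cand = (0,) + rest
            if cand != identity:
                out.append(cand)
    else:
        for cand in combinations(range(n), n_test):
            if cand != identity:
                out.append(cand)
    return out


def n_balanced_relabelings(n_test: int, n_ref: int) -> int:
    """Closed-form count matching :func:`balanced_relabelings`."""
    if n_test == n_ref:
        return math.comb(n_test + n_ref - 1, n_test - 1) - 1
    return math.comb(n_test + n_ref, n_test) - 1


def _contrast_arrays(matrix: ExpressionMatrix, contrast: Contrast):
    a = matrix.group_values(contrast.test_group)
    b = matrix.group_values(contrast.reference_group)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise PermdegError(
            f"contrast {contrast} needs >=2 samples per group "
            f"(got {a.shape[1]} vs {b.shape[1]})"
        )
    return a, b


def build_null(
    matrix: ExpressionMatrix,
    contrast: Contrast,
    n_permutations: int = 1000,
    seed: int = 0,
    combination: str = "stouffer",
) -> NullDistributions:
    """Pool permuted t / median-difference / log2FC statistics across genes.

    Exhaustive enumeration is used whenever the design admits at most
    ``n_permutations`` distinct balanced relabelings (always the case
    for duplicate designs); otherwise a seeded random subset is drawn.
    """
    if n_permutations < 1:
        raise PermdegError("n_permutations must be >= 1")
    a, b = _contrast_arrays(matrix, contrast)
    na, nb = a.shape[1], b.shape[1]
    pooled = np.hstack([a, b])
    total = n_balanced_relabelings(na, nb)
    if total <= max(n_permutations, 100_000):
        relabs = balanced_relabelings(na, nb)
        if len(relabs) > n_permutations:
            rng = np.random.default_rng(seed)
            keep = rng.choice(len(relabs), size=n_permutations, replace=False)
            relabs = [relabs[i] for i in sorted(keep)]
            scheme = f"random_subset:{n_permutations}"
        else:
            scheme = f"exhaustive:{len(relabs)}"
    else:  # pragma: no cover - designs that large are out of scope here
        rng = np.random.default_rng(seed)
        relabs = []
        identity = tuple(range(na))
        while len(relabs) < n_permutations:
            cand = tuple(sorted(rng.choice(na + nb, size=na, replace=False)))
            if cand != identity:
                relabs.append(cand)
        scheme = f"random:{n_permutations}"

    all_idx = set(range(na + nb))
    t_list, md_list, fc_list = [], [], []
    for test_idx in relabs:
        ref_idx = sorted(all_idx - set(test_idx))
        t, _, md, fc = _row_stats(pooled[:, list(test_idx)], pooled[:, ref_idx])
        t_list.append(t)
        md_list.append(md)
        fc_list.append(fc)

    null_t = np.concatenate(t_list)
    null_md = np.concatenate(md_list)
    null_fc = np.concatenate(fc_list)
    df = na + nb - 2
    p_t = 2.0 * stats.t.sf(np.abs(null_t), df)
    p_t = np.where(np.isinf(null_t), 0.0, p_t)
    p_md = _empirical_pvalues(null_md, null_md, two_sided=True)
    z, _ = combine_pvalues(p_t, p_md, method=combination)
    return NullDistributions(
        null_t=null_t,
        null_md=null_md,
        null_log2fc=null_fc,
        null_combined_z=np.asarray(z, dtype=float),
        n_permutations=len(relabs),
        scheme=scheme,
        df=df,
    )


def _empirical_pvalues(
    observed: np.ndarray, null_values: np.ndarray, two_sided: bool
) -> np.ndarray:
    """Add-one-smoothed empirical p-values of ``observed`` against a null.

    Two-sided compares absolute values; one-sided treats larger observed
    values as more significant.
    """
    obs = np.asarray(observed, dtype=float)
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise PermdegError("empirical p-value needs a non-empty null")
    if two_sided:
        ref = np.sort(np.abs(null))
        query = np.abs(obs)
    else:
        ref = np.sort(null)
        query = obs
    n = ref.size
    count_ge = n - np.searchsorted(ref, query, side="left")
    return (count_ge + 1.0) / (n + 1.0)


def empirical_p(observed: float, null_values, two_sided: bool = True) -> float:
    """p = (#{null at least as extreme} + 1) / (N + 1), guaranteed in (0, 1]."""
    return float(_empirical_pvalues(np.array([observed]), null_values, two_sided)[0])


def combine_pvalues(p_t, p_md, method: str = "stouffer"):
    """Combine two p-values into a single z and p (vectorized).

    Stouffer (default): z_i = Phi^{-1}(1 - p_i), combined
    z = (z_t + z_md)/sqrt(2), combined p = 1 - Phi(z).  Fisher's method
    is available as an alternative; its combined p is mapped back to a
    z on the normal scale so downstream ranking is method-agnostic.
    Inputs are clamped to [1e-15, 1 - 1e-15].
    """
    pt = np.clip(np.asarray(p_t, dtype=float), _P_CLAMP, 1.0 - _P_CLAMP)
    pm = np.clip(np.asarray(p_md, dtype=float), _P_CLAMP, 1.0 - _P_CLAMP)
    if method == "stouffer":
        z = (stats.norm.isf(pt) + stats.norm.isf(pm)) / _SQRT2
        p = stats.norm.sf(z)
    elif method == "fisher":
        x = -2.0 * (np.log(pt) + np.log(pm))
        p = stats.chi2.sf(x, df=4)
        z = stats.norm.isf(np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP))
    else:
        raise PermdegError(f"unknown combination method {method!r}")
    if np.isscalar(p_t) and np.isscalar(p_md):
        return float(z), float(p)
    return z, p


def adjusted_pvalues(
    matrix: ExpressionMatrix,
    contrast: Contrast,
    null: NullDistributions,
    combination: str = "stouffer",
) -> pd.Series:
    """Permutation-adjusted p per gene: the one-sided empirical p of the
    gene's combined z against the pooled null of combined z values."""
    a, b = _contrast_arrays(matrix, contrast)
    _, p_t, md, _ = _row_stats(a, b)
    p_md = _empirical_pvalues(md, null.null_md, two_sided=True)
    z, _ = combine_pvalues(p_t, p_md, method=combination)
    adj = _empirical_pvalues(z, null.null_combined_z, two_sided=False)
    return pd.Series(adj, index=matrix.gene_ids, name="adjusted_p")


def fc_cutoff(null_log2fc, level: float = 0.95) -> float:
    """The ``level`` quantile of |permuted log2FC| (linear interpolation)."""
    null = np.asarray(null_log2fc, dtype=float)
    if null.size == 0:
        raise PermdegError("fold-change cutoff needs a non-empty null")
    if not 0.0 < level < 1.0:
        raise PermdegError("quantile level must lie in (0, 1)")
    return float(np.quantile(np.abs(null), level))


def call_degs(
    stats_table: pd.DataFrame,
    contrast: Contrast,
    alpha: float = 0.05,
    cutoff: float = 0.0,
) -> DegSet:
    """Call genes with adjusted_p < alpha AND |log2fc| > cutoff (strict)."""
    if cutoff < 0:
        raise PermdegError("fold-change cutoff must be >= 0")
    sig = (stats_table["adjusted_p"] < alpha) & (stats_table["log2fc"].abs() > cutoff)
    genes = {
        g: ("up" if fc > 0 else "down")
        for g, fc in stats_table.loc[sig, "log2fc"].items()
    }
    return DegSet(
        contrast=contrast,
        alpha=alpha,
        fc_cutoff=cutoff,
        genes=genes,
        universe=frozenset(stats_table.index),
    )


def test_contrast(
    matrix: ExpressionMatrix,
    contrast: Contrast,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    fc_quantile: float = 0.95,
    combination: str = "stouffer",
) -> DegResult:
    """Run the full integrative test for one contrast.

    Returns per-gene statistics (t, median difference, log2FC, combined
    z, permutation-adjusted p, BH q of the adjusted p), the pooled null
    distributions, the derived fold-change cutoff, and the called DEG
    set.
    """
    a, b = _contrast_arrays(matrix, contrast)
    null = build_null(matrix, contrast, n_permutations, seed, combination)
    t, p_t, md, fc = _row_stats(a, b)
    p_md = _empirical_pvalues(md, null.null_md, two_sided=True)
    z, _ = combine_pvalues(p_t, p_md, method=combination)
    adj = _empirical_pvalues(z, null.null_combined_z, two_sided=False)
    bh_q = stats.false_discovery_control(adj, method="bh")
    cutoff = fc_cutoff(null.null_log2fc, fc_quantile)
    table = pd.DataFrame(
        {
            "t_stat": t,
            "p_t": p_t,
            "median_diff": md,
            "p_md": p_md,
            "log2fc": fc,
            "combined_z": z,
            "adjusted_p": adj,
            "bh_q": bh_q,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )
    degs = call_degs(table, contrast, alpha=alpha, cutoff=cutoff)
    table["is_deg"] = table.index.isin(degs.genes)
    table["direction"] = [degs.genes.get(g, "") for g in table.index]
    return DegResult(
        contrast=contrast, stats=table, null=null, fc_cutoff=cutoff, deg_set=degs
    )


# the name describes a statistical contrast, not a pytest case
test_contrast.__test__ = False
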