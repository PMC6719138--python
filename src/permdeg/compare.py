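"""Comparing two DEG sets: sign-pattern clusters, Venn counts, overlap tests.

When the same reference condition is contrasted against two different
perturbations, every gene differential in at least one contrast falls
into one of seven direction patterns:

1. up in both contrasts            5. down only in contrast 1
2. up only in contrast 1           6. down only in contrast 2
3. discordant (up in one,          7. down in both contrasts
   down in the other)
4. up only in contrast 2

Overlap significance is assessed with a one-sided (enrichment) Fisher's
exact test over the tested gene universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .degtest import DegSet
from .matrix import PermdegError

__all__ = [
    "CLUSTER_LABELS",
    "ClusterAssignment",
    "OverlapTest",
    "assign_clusters",
    "venn_counts",
    "overlap_fisher",
    "dependency_fractions",
]

CLUSTER_LABELS: dict[int, str] = {
    1: "up in both",
    2: "up only in contrast 1",
    3: "discordant",
    4: "up only in contrast 2",
    5: "down only in contrast 1",
    6: "down only in contrast 2",
    7: "down in both",
}


@dataclass
class ClusterAssignment:
    """gene_id -> cluster id (1..7) over the union of two DEG sets."""

    clusters: dict[str, int]
    labels: dict[int, str]

    def counts(self) -> dict[int, int]:
        out = {c: 0 for c in range(1, 8)}
        for c in self.clusters.values():
            out[c] += 1
        return out

    def genes_in(self, cluster_id: int) -> set[str]:
        return {g for g, c in self.clusters.items() if c == cluster_id}


@dataclass
class OverlapTest:
    """One-sided Fisher's exact test of two gene sets over a universe.

    ``table`` is ((in A & in B, in A & not B), (not A & in B, neither)).
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    sidedness: str = "greater"


def _check_same_universe(deg_a: DegSet, deg_b: DegSet) -> None:
    if deg_a.universe and deg_b.universe and deg_a.universe != deg_b.universe:
        raise PermdegError("DEG sets were called over different gene universes")


def assign_clusters(deg_a: DegSet, deg_b: DegSet) -> ClusterAssignment:
    """Assign every gene in the union of the two DEG sets to one cluster."""
    _check_same_universe(deg_a, deg_b)
    clusters: dict[str, int] = {}
    for gene in deg_a.gene_set() | deg_b.gene_set():
        da = deg_a.genes.get(gene)
        db = deg_b.genes.get(gene)
        if da == "up" and db == "up":
            c = 1
        elif da == "up" and db is None:
            c = 2
        elif {da, db} == {"up", "down"}:
            c = 3
        elif da is None and db == "up":
            c = 4
        elif da == "down" and db is None:
            c = 5
        elif da is None and db == "down":
            c = 6
        else:  # down in both
            c = 7
        clusters[gene] = c
    return ClusterAssignment(clusters=clusters, labels=dict(CLUSTER_LABELS))


def venn_counts(deg_a: DegSet, deg_b: DegSet) -> tuple[int, int, int]:
    """(only in A, only in B, in both)."""
    _check_same_universe(deg_a, deg_b)
    a, b = deg_a.gene_set(), deg_b.gene_set()
    both = len(a & b)
    return len(a) - both, len(b) - both, both


def overlap_fisher(deg_a: DegSet, deg_b: DegSet, universe_size: int) -> OverlapTest:
    """One-sided (enrichment) Fisher's exact test of the 2x2 membership table."""
    _check_same_universe(deg_a, deg_b)
    a, b = deg_a.gene_set(), deg_b.gene_set()
    n11 = len(a & b)
    n10 = len(a) - n11
    n01 = len(b) - n11
    n00 = universe_size - n11 - n10 - n01
    if n00 < 0:
        raise PermdegError(
            f"universe ({universe_size}) smaller than the union ({n11 + n10 + n01})"
        )
    _, p = stats.fisher_exact([[n11, n10], [n01, n00]], alternative="greater")
    if n10 * n01 == 0:
        odds = np.inf if n11 * n00 > 0 else np.nan
    else:
        odds = (n11 * n00) / (n10 * n01)
    return OverlapTest(
        table=((n11, n10), (n01, n00)),
        odds_ratio=float(odds),
        p_value=float(p),
        sidedness="greater",
    )


def dependency_fractions(
    deg_a: DegSet,
    deg_b: DegSet,
    universe_size: int,
    denominator_mode: str = "union",
) -> tuple[float, float]:
    """Fractions of genes dependent on either-but-not-both vs on both.

    With ``denominator_mode="union"`` (default) the fractions are of the
    union of the two DEG sets; with ``"universe"`` they are of the full
    tested universe of ``universe_size`` genes.
    """
    if universe_size <= 0:
        raise PermdegError("universe_size must be positive")
    _check_same_universe(deg_a, deg_b)
    only_a, only_b, both = venn_counts(deg_a, deg_b)
    union = only_a + only_b + both
    if denominator_mode == "union":
        if union == 0:
            raise PermdegError("union of DEG sets is empty; no fractions to report")
        denom = union
    elif denominator_mode == "universe":
        denom = universe_size
    else:
        raise PermdegError(f"unknown denominator_mode {denominator_mode!r}")
    return (only_a + only_b) / denom, both / denom
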