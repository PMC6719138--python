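"""Hypergeometric over-representation analysis against GMT gene sets.

For a query gene list (typically one direction-pattern cluster) and a
collection of gene sets, each term is scored with the hypergeometric
upper-tail probability of drawing at least the observed number of term
members in a query of that size from the tested universe.  Terms are
kept when p < 0.05 and the query contains more than two term members,
the conventional reporting filter for cluster-level enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .matrix import PermdegError

__all__ = [
    "GeneSetCollection",
    "EnrichmentRecord",
    "read_gmt",
    "hypergeom_enrich",
    "filter_terms",
    "records_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """term_id -> (term name, member gene ids)."""

    sets: dict[str, tuple[str, frozenset]]

    def __len__(self) -> int:
        return len(self.sets)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, members in self.sets.values():
            out |= members
        return out


@dataclass
class EnrichmentRecord:
    """One term's over-representation result.

    k = query∩term, K = term size in universe, n = query size,
    N = universe size; fold_enrichment = (k/n)/(K/N).
    """

    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    fold_enrichment: float
    p_value: float


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: term, description, then member genes, tab-separated."""
    sets: dict[str, tuple[str, frozenset]] = {}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise PermdegError(
                f"{path}: line {lineno}: GMT lines need >=3 tab-separated fields"
            )
        term_id, description = fields[0], fields[1]
        members = [g for g in fields[2:] if g]
        unique = frozenset(members)
        if len(unique) < len(members):
            logger.warning(
                "%s: line %d: duplicate member genes in term %s deduplicated",
                path, lineno, term_id,
            )
        if not unique:
            raise PermdegError(f"{path}: line {lineno}: term {term_id} has no members")
        sets[term_id] = (description, unique)
    return GeneSetCollection(sets=sets)


def hypergeom_enrich(
    query, collection: GeneSetCollection, universe
) -> list[EnrichmentRecord]:
    """Score every term; records sorted by ascending p-value.

    Term member lists are intersected with the universe before testing;
    the query must be a subset of the universe.
    """
    universe = set(universe)
    if not universe:
        raise PermdegError("enrichment universe is empty")
    query = set(query)
    stray = query - universe
    if stray:
        raise PermdegError(
            f"query genes outside the universe: {sorted(stray)[:5]}"
        )
    N, n = len(universe), len(query)
    records = []
    for term_id, (name, members) in collection.sets.items():
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(query & in_universe)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n > 0 else 0.0
        records.append(
            EnrichmentRecord(
                term_id=term_id,
                term_name=name,
                k=k,
                K=K,
                n=n,
                N=N,
                fold_enrichment=fold,
                p_value=min(p, 1.0),
            )
        )
    records.sort(key=lambda r: (r.p_value, r.term_id))
    return records


def filter_terms(
    records: list[EnrichmentRecord], p_max: float = 0.05, min_count: int = 3
) -> list[EnrichmentRecord]:
    """Keep terms with p_value < p_max and query hit count >= min_count."""
    return [r for r in records if r.p_value < p_max and r.k >= min_count]


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Tabulate records, adding Benjamini-Hochberg q-values and the kept flag."""
    frame = pd.DataFrame(
        [
            (r.term_id, r.term_name, r.k, r.K, r.n, r.N, r.fold_enrichment, r.p_value)
            for r in records
        ],
        columns=[
            "term_id", "term_name", "k", "K", "n", "N", "fold_enrichment", "p_value",
        ],
    )
    if len(frame):
        frame["bh_q"] = stats.false_discovery_control(frame["p_value"], method="bh")
        kept = {r.term_id for r in filter_terms(records)}
        frame["kept"] = frame["term_id"].isin(kept)
    else:
        frame["bh_q"] = pd.Series(dtype=float)
        frame["kept"] = pd.Series(dtype=bool)
    return frame
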