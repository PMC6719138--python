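"""The gene-by-sample expression container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PermdegError(Exception):
    """Base class for all errors raised by this package."""


@dataclass
class ExpressionMatrix:
    """A genes × samples matrix of (log2) intensities plus a sample design.

    Parameters
    ----------
    values
        DataFrame with unique gene identifiers as the index and unique
        sample identifiers as columns.  All entries must be finite.
    design
        Mapping from each sample identifier to its condition group label
        (e.g. ``WT``, ``KD1``).  Every column of ``values`` must appear.
    """

    values: pd.DataFrame
    design: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise PermdegError(f"duplicate gene ids: {list(dupes)[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise PermdegError(f"duplicate sample ids: {list(dupes)[:5]}")
        self.design = dict(self.design)
        missing = [s for s in self.values.columns if s not in self.design]
        if missing:
            raise PermdegError(f"samples missing from design: {missing}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise PermdegError(
                "non-finite value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def groups(self) -> list[str]:
        """Group labels in first-appearance (column) order."""
        seen: list[str] = []
        for s in self.values.columns:
            g = self.design[s]
            if g not in seen:
                seen.append(g)
        return seen

    def group_samples(self, group: str) -> list[str]:
        """Sample ids belonging to ``group``, in column order."""
        out = [s for s in self.values.columns if self.design[s] == group]
        if not out:
            raise PermdegError(f"no samples in group {group!r}")
        return out

    def group_values(self, group: str) -> np.ndarray:
        """Float array of shape (n_genes, n_samples_in_group)."""
        return self.values[self.group_samples(group)].to_numpy(dtype=float)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)].copy(), dict(self.design))

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), dict(self.design))
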