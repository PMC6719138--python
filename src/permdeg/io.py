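"""TSV/JSON readers and writers for every pipeline artifact.

The expression dialect is genes-in-rows: first column gene ids, header
row of sample ids; the design is a separate two-column TSV
(sample_id, group).  All files are UTF-8, uncompressed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, PermdegError
from .preprocess import GmmFit
from .simulate import GroundTruth

__all__ = [
    "read_design_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "write_design_tsv",
    "read_truth_tsv",
    "write_truth_tsv",
    "write_gmm_json",
    "read_gmm_json",
    "write_json",
]


def read_design_tsv(path) -> dict[str, str]:
    """Two-column TSV (sample_id, group) -> mapping."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise PermdegError(f"{path}: design needs two columns (sample_id, group)")
    sample_col, group_col = frame.columns[:2]
    if frame[sample_col].duplicated().any():
        dupes = frame.loc[frame[sample_col].duplicated(), sample_col].tolist()
        raise PermdegError(f"{path}: duplicate sample ids in design: {dupes}")
    return dict(zip(frame[sample_col], frame[group_col]))


def read_expression_tsv(matrix_path, design_path=None, design=None) -> ExpressionMatrix:
    """Read a genes-in-rows expression TSV plus its sample design.

    Errors name the offending coordinates: duplicate gene ids, samples
    absent from the design, and non-numeric cells are all rejected.
    """
    frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise PermdegError(f"{matrix_path}: duplicated gene ids: {dupes[:5]}")
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
            gene = bad.index[0] if len(bad) else "?"
            raise PermdegError(
                f"{matrix_path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
    if design is None:
        if design_path is None:
            raise PermdegError("a design mapping or design TSV path is required")
        design = read_design_tsv(design_path)
    missing = [s for s in frame.columns if s not in design]
    if missing:
        raise PermdegError(f"samples in matrix but not in design: {missing}")
    return ExpressionMatrix(frame, {s: design[s] for s in frame.columns})


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def write_design_tsv(matrix: ExpressionMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tgroup\n")
        for sample in matrix.sample_ids:
            fh.write(f"{sample}\t{matrix.design[sample]}\n")


def write_truth_tsv(truth: GroundTruth, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    truth.table.to_csv(path, sep="\t", index_label="gene_id")


def read_truth_tsv(path) -> GroundTruth:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame["is_expressed"] = frame["is_expressed"].astype(bool)
    frame["pattern_id"] = frame["pattern_id"].astype(int)
    return GroundTruth(frame)


def write_gmm_json(fit: GmmFit, path) -> None:
    write_json(fit.to_dict(), path)


def read_gmm_json(path) -> GmmFit:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return GmmFit(
        weights=tuple(d["weights"]),
        means=tuple(d["means"]),
        sds=tuple(d["sds"]),
        log_likelihood=d["log_likelihood"],
        n_iter=d["n_iter"],
        converged=d["converged"],
        threshold=d["threshold"],
    )


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
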