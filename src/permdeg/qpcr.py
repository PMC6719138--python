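"""Relative RT-qPCR quantification by the 2^-ddCt method.

dCt = Ct(target) - Ct(reference gene); ddCt = dCt(sample) - dCt(control);
relative expression = 2^-ddCt.  Technical replicates are averaged on the
Ct (cycle) scale before differencing, and the control dCt is the mean
over all control samples.  Amplification efficiency is fixed at 2.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .matrix import PermdegError

__all__ = ["delta_ct", "ddct_fold", "quantify", "read_ct_table", "write_ct_table"]

CT_COLUMNS = ["sample_id", "condition", "gene", "ct", "replicate"]


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """Ct of the target gene minus Ct of the reference gene."""
    return float(ct_target) - float(ct_reference)


def ddct_fold(dct_sample: float, dct_control: float) -> float:
    """Relative expression 2^-(dCt_sample - dCt_control)."""
    return float(2.0 ** -(float(dct_sample) - float(dct_control)))


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise PermdegError(f"Ct table missing columns: {missing}")
    if (table["ct"] <= 0).any():
        raise PermdegError("Ct values must be positive cycle counts")
    bad_gene = set(table["gene"]) - {"target", "reference"}
    if bad_gene:
        raise PermdegError(f"gene column must be target/reference, got {sorted(bad_gene)}")
    bad_cond = set(table["condition"]) - {"control", "treated"}
    if bad_cond:
        raise PermdegError(
            f"condition column must be control/treated, got {sorted(bad_cond)}"
        )
    return table


def quantify(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample fold changes and a per-condition mean +/- sd summary.

    Technical replicates are averaged on the Ct scale per (sample, gene),
    then dCt is formed per sample and referred to the mean control dCt.
    Returns ``(per_sample, summary)`` where ``per_sample`` has columns
    sample_id, condition, delta_ct, ddct, fold.
    """
    table = _validate_table(table)
    mean_ct = (
        table.groupby(["sample_id", "condition", "gene"], sort=False)["ct"]
        .mean()
        .unstack("gene")
    )
    for gene in ("target", "reference"):
        if gene not in mean_ct.columns or mean_ct[gene].isna().any():
            bad = (
                mean_ct.index.get_level_values("sample_id").tolist()
                if gene not in mean_ct.columns
                else mean_ct.index[mean_ct[gene].isna()].get_level_values("sample_id").tolist()
            )
            raise PermdegError(f"samples missing a {gene} measurement: {bad}")
    dct = mean_ct["target"] - mean_ct["reference"]
    per_sample = dct.reset_index().rename(columns={0: "delta_ct"})
    per_sample.columns = ["sample_id", "condition", "delta_ct"]
    controls = per_sample.loc[per_sample["condition"] == "control", "delta_ct"]
    if controls.empty:
        raise PermdegError("Ct table contains no control samples")
    dct_control = float(controls.mean())
    per_sample["ddct"] = per_sample["delta_ct"] - dct_control
    per_sample["fold"] = 2.0 ** -per_sample["ddct"]
    summary = (
        per_sample.groupby("condition", sort=False)["fold"]
        .agg(["mean", "std", "count"])
        .rename(columns={"mean": "fold_mean", "std": "fold_sd", "count": "n_samples"})
        .reset_index()
    )
    return per_sample, summary


def read_ct_table(path) -> pd.DataFrame:
    """Read a Ct TSV with the fixed columns sample_id, condition, gene, ct, replicate."""
    table = pd.read_csv(path, sep="\t")
    return _validate_table(table)


def write_ct_table(table: pd.DataFrame, path) -> None:
    _validate_table(table)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
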