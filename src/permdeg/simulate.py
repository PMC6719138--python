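"""Synthetic expression matrices, qPCR tables and ground truth.

The generator emulates the structure of a small-replicate knockdown
microarray study: three conditions (wild type plus two knockdowns), two
arrays per condition, per-gene baseline log2 intensities drawn from a
two-component unexpressed/expressed Gaussian mixture, i.i.d. Gaussian
replicate noise, and a configurable set of spiked differentially
expressed genes arranged in the seven up/down/unique/common/discordant
patterns used when two knockdown contrasts are compared:

====  ============================  =========================
id    pattern                       effect signs (KD1, KD2)
====  ============================  =========================
1     up in both knockdowns         (+, +)
2     up only in KD1                (+, 0)
3     discordant (up KD1, down KD2) (+, -)
4     up only in KD2                (0, +)
5     down only in KD1              (-, 0)
6     down only in KD2              (0, -)
7     down in both knockdowns       (-, -)
====  ============================  =========================

Effects are applied additively on the log2 scale.  All randomness flows
from one explicitly seeded generator per call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, PermdegError

__all__ = [
    "PATTERN_SIGNS",
    "SimConfig",
    "GroundTruth",
    "simulate_matrix",
    "simulate_null_matrix",
    "simulate_qpcr",
]

#: pattern id -> (sign of the KD1 effect, sign of the KD2 effect)
PATTERN_SIGNS: dict[int, tuple[int, int]] = {
    1: (+1, +1),
    2: (+1, 0),
    3: (+1, -1),
    4: (0, +1),
    5: (-1, 0),
    6: (0, -1),
    7: (-1, -1),
}


def _default_spike_table() -> list[tuple[int, int, float]]:
    # 60 genes per pattern at 2.0 log2 units: with ~50% of 2000 genes
    # expressed this regulates roughly 30% of the expressed universe per
    # knockdown contrast, the signal density of a strong knockdown.
    return [(p, 60, 2.0) for p in range(1, 8)]


@dataclass
class SimConfig:
    """Study conditions for the expression-matrix generator.

    ``spike_table`` rows are ``(pattern_id, count, effect_size)`` with
    the pattern semantics of :data:`PATTERN_SIGNS`; effect sizes are in
    log2 units and applied additively.  The first group is the
    reference; KD1/KD2 effects apply to the second and third groups.
    """

    n_genes: int = 2000
    groups: tuple[str, ...] = ("WT", "KD1", "KD2")
    replicates_per_group: int = 2
    mix_weight_expressed: float = 0.5
    mu_unexpressed: float = 3.0
    sigma_unexpressed: float = 0.5
    mu_expressed: float = 8.0
    sigma_expressed: float = 1.0
    replicate_sd: float = 0.25
    spike_table: list[tuple[int, int, float]] = field(default_factory=_default_spike_table)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.replicates_per_group <= 0:
            raise PermdegError("n_genes and replicates_per_group must be positive")
        if len(self.groups) < 2 or len(set(self.groups)) != len(self.groups):
            raise PermdegError("groups must be >=2 distinct labels")
        if not 0.0 <= self.mix_weight_expressed <= 1.0:
            raise PermdegError("mix_weight_expressed must lie in [0, 1]")
        if min(self.sigma_unexpressed, self.sigma_expressed) <= 0:
            raise PermdegError("mixture sigmas must be positive")
        if self.replicate_sd < 0:
            raise PermdegError("replicate_sd must be non-negative")
        for pattern, count, effect in self.spike_table:
            if pattern not in PATTERN_SIGNS:
                raise PermdegError(f"unknown spike pattern id {pattern!r}")
            if count < 0:
                raise PermdegError("spike counts must be non-negative")
            if effect < 0:
                raise PermdegError("spike effect sizes must be non-negative")
        if self.total_spikes > self.n_genes:
            raise PermdegError(
                f"spike table requests {self.total_spikes} genes but only "
                f"{self.n_genes} are simulated"
            )

    @property
    def total_spikes(self) -> int:
        return sum(count for _, count, _ in self.spike_table)


@dataclass
class GroundTruth:
    """Per-gene truth labels written alongside every simulated matrix.

    ``table`` is indexed by gene id with columns ``is_expressed``
    (mixture component the baseline was drawn from), ``pattern_id``
    (1-7, or 0 for an unspiked gene) and the true additive log2 effects
    ``true_log2fc_kd1`` / ``true_log2fc_kd2``.
    """

    table: pd.DataFrame

    def true_degs(self, contrast: str) -> dict[str, int]:
        """Spiked genes with a non-zero effect in ``contrast`` (kd1|kd2).

        Returns gene id -> effect sign (+1 up, -1 down).
        """
        col = {"kd1": "true_log2fc_kd1", "kd2": "true_log2fc_kd2"}[contrast.lower()]
        fc = self.table[col]
        hit = fc[fc != 0.0]
        return {g: int(np.sign(v)) for g, v in hit.items()}


def simulate_matrix(config: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one expression matrix and its ground truth from ``config``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"G{i:06d}" for i in range(1, n + 1)]

    is_expressed = rng.random(n) < config.mix_weight_expressed
    mu = np.where(is_expressed, config.mu_expressed, config.mu_unexpressed)
    sigma = np.where(is_expressed, config.sigma_expressed, config.sigma_unexpressed)
    baseline = rng.normal(mu, sigma)

    pattern_id = np.zeros(n, dtype=int)
    fc_kd1 = np.zeros(n)
    fc_kd2 = np.zeros(n)
    total = config.total_spikes
    if total:
        expressed_idx = np.flatnonzero(is_expressed)
        if expressed_idx.size < total:
            raise PermdegError(
                f"cannot place {total} spiked genes among {expressed_idx.size} "
                "expressed genes; raise n_genes or mix_weight_expressed"
            )
        chosen = rng.choice(expressed_idx, size=total, replace=False)
        pos = 0
        for pattern, count, effect in config.spike_table:
            s1, s2 = PATTERN_SIGNS[pattern]
            idx = chosen[pos : pos + count]
            pattern_id[idx] = pattern
            fc_kd1[idx] = s1 * effect
            fc_kd2[idx] = s2 * effect
            pos += count

    r = config.replicates_per_group
    columns: list[str] = []
    design: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    for gi, group in enumerate(config.groups):
        if gi == 1:
            shift = fc_kd1
        elif gi == 2:
            shift = fc_kd2
        else:
            shift = np.zeros(n)
        block = (baseline + shift)[:, None] + rng.normal(0.0, config.replicate_sd, (n, r))
        blocks.append(block)
        for rep in range(1, r + 1):
            sid = f"{group}_{rep}"
            columns.append(sid)
            design[sid] = group

    values = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(gene_ids, name="gene_id"), columns=columns
    )
    truth = pd.DataFrame(
        {
            "is_expressed": is_expressed,
            "pattern_id": pattern_id,
            "true_log2fc_kd1": fc_kd1,
            "true_log2fc_kd2": fc_kd2,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return ExpressionMatrix(values, design), GroundTruth(truth)


def simulate_null_matrix(config: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """As :func:`simulate_matrix` with an empty spike table (no true DEGs)."""
    cfg = SimConfig(
        n_genes=config.n_genes,
        groups=config.groups,
        replicates_per_group=config.replicates_per_group,
        mix_weight_expressed=config.mix_weight_expressed,
        mu_unexpressed=config.mu_unexpressed,
        sigma_unexpressed=config.sigma_unexpressed,
        mu_expressed=config.mu_expressed,
        sigma_expressed=config.sigma_expressed,
        replicate_sd=config.replicate_sd,
        spike_table=[],
        seed=config.seed,
    )
    return simulate_matrix(cfg)


def simulate_qpcr(
    n_samples: int,
    true_fold: float,
    ct_ref_mean: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    dct_control: float = 2.0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Simulate a Ct table for relative quantification by 2^-ddCt.

    Generates ``n_samples`` control and ``n_samples`` treated samples,
    each with target- and reference-gene cycle thresholds; the treated
    target Ct is shifted by ``-log2(true_fold)`` so that noiseless
    quantification recovers ``true_fold`` exactly.  Every Ct measurement
    carries independent ``Normal(0, noise_sd)`` noise.
    """
    if true_fold <= 0:
        raise PermdegError(f"true_fold must be positive, got {true_fold!r}")
    if n_samples <= 0 or n_replicates <= 0:
        raise PermdegError("n_samples and n_replicates must be positive")
    rng = np.random.default_rng(seed)
    shift = -math.log2(true_fold)
    rows = []
    for condition, target_offset in (("control", 0.0), ("treated", shift)):
        for i in range(1, n_samples + 1):
            sid = f"{condition}_{i}"
            for rep in range(1, n_replicates + 1):
                rows.append(
                    (sid, condition, "reference", ct_ref_mean + rng.normal(0, noise_sd), rep)
                )
                rows.append(
                    (
                        sid,
                        condition,
                        "target",
                        ct_ref_mean + dct_control + target_offset + rng.normal(0, noise_sd),
                        rep,
                    )
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "gene", "ct", "replicate"]
    )
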