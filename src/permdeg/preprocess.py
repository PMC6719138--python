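"""Normalization and expressed-gene gating.

Two steps prepare an intensity matrix for differential testing:

1. quantile normalization, forcing every sample onto a common intensity
   distribution (the mean of the per-sample sorted vectors) while
   preserving within-sample ranks;
2. a two-component Gaussian mixture fitted to the pooled log2
   intensities, whose equal-density crossing separates the unexpressed
   background component from the expressed component.  Genes exceeding
   the crossing in at least one sample form the expressed universe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .matrix import ExpressionMatrix, PermdegError

__all__ = [
    "GmmFit",
    "log2_transform",
    "quantile_normalize",
    "fit_expression_gmm",
    "select_expressed",
]

_SD_FLOOR = 1e-3
_EM_TOL = 1e-6
_EM_MAX_ITER = 500


@dataclass
class GmmFit:
    """Two-component 1-D Gaussian mixture fit and the derived expression gate.

    Components are ordered by ascending mean: index 0 is the unexpressed
    background, index 1 the expressed signal.  ``threshold`` is the log2
    intensity strictly between the two means where the weighted component
    densities are equal (the posterior-0.5 crossing).
    """

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    log_likelihood: float
    n_iter: int
    converged: bool
    threshold: float
    ll_trace: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.means[0] < self.means[1]:
            raise PermdegError("mixture means must be strictly ordered")
        if not (self.means[0] < self.threshold < self.means[1]):
            raise PermdegError("threshold must lie strictly between the component means")

    def to_dict(self) -> dict:
        return {
            "weights": list(self.weights),
            "means": list(self.means),
            "sds": list(self.sds),
            "log_likelihood": self.log_likelihood,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "threshold": self.threshold,
            # rendered the way array thresholds are conventionally reported
            "threshold_4dp": f"{self.threshold:.4f}",
        }


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every intensity by its base-2 logarithm.

    Raises an error naming the first offending gene/sample if any value
    is non-positive.
    """
    arr = matrix.values.to_numpy(dtype=float)
    bad = np.argwhere(arr <= 0)
    if bad.size:
        g, s = bad[0]
        raise PermdegError(
            f"log2 transform requires positive intensities; value {arr[g, s]!r} "
            f"at gene {matrix.values.index[g]!r}, sample {matrix.values.columns[s]!r}"
        )
    out = pd.DataFrame(
        np.log2(arr), index=matrix.values.index, columns=matrix.values.columns
    )
    return ExpressionMatrix(out, dict(matrix.design))


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples against the mean of sorted columns.

    Every sample's sorted value vector becomes the cross-sample mean of
    sorted vectors; each gene keeps its within-sample rank.  Ties within
    a sample receive the mean of the reference values at their rank
    positions (average-rank interpolation, the limma convention).
    """
    if matrix.n_samples < 2:
        raise PermdegError("quantile normalization needs at least 2 samples")
    arr = matrix.values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise PermdegError("missing values are not supported (no imputation)")
    n = arr.shape[0]
    reference = np.sort(arr, axis=0).mean(axis=1)
    positions = np.arange(1, n + 1, dtype=float)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(frame, dict(matrix.design))


def _mixture_logpdf(x: np.ndarray, w, mu, sd) -> np.ndarray:
    comp = np.stack(
        [np.log(w[k]) + stats.norm.logpdf(x, mu[k], sd[k]) for k in range(2)]
    )
    return comp, np.logaddexp(comp[0], comp[1])


def equal_density_threshold(weights, means, sds) -> float:
    """Intensity between the two means where the weighted densities cross.

    Solved numerically with a bracketing root find on a dense grid, so it
    is robust to very unequal weights.
    """
    lo, hi = float(means[0]), float(means[1])

    def g(x):
        return (
            np.log(weights[0]) + stats.norm.logpdf(x, means[0], sds[0])
            - np.log(weights[1]) - stats.norm.logpdf(x, means[1], sds[1])
        )

    grid = np.linspace(lo, hi, 2048)
    vals = g(grid)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        raise PermdegError("no equal-density crossing between the component means")
    i = sign_change[0]
    return float(optimize.brentq(g, grid[i], grid[i + 1]))


def fit_expression_gmm(values, seed: int | None = None) -> GmmFit:
    """Fit a two-component Gaussian mixture to pooled log2 intensities.

    EM with deterministic initialization at the 25th/75th percentiles and
    equal weights; convergence at relative log-likelihood change below
    1e-6, at most 500 iterations.  A component whose standard deviation
    falls under 1e-3 is treated as collapsed and raises an error.  The
    ``seed`` parameter is accepted for interface stability; the default
    quantile initialization is deterministic and does not consume it.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 100:
        raise PermdegError(
            f"need at least 100 values to fit the expression mixture, got {x.size}"
        )
    if not np.all(np.isfinite(x)):
        raise PermdegError("non-finite values in mixture input")
    if np.std(x) < _SD_FLOOR:
        raise PermdegError("degenerate input: all intensities (nearly) identical")

    mu = np.percentile(x, [25.0, 75.0]).astype(float)
    if mu[1] - mu[0] < _SD_FLOOR:
        spread = max(np.std(x), _SD_FLOOR)
        mu = np.array([x.mean() - spread, x.mean() + spread])
    sd = np.full(2, max(np.std(x) / 2.0, _SD_FLOOR))
    w = np.array([0.5, 0.5])

    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, _EM_MAX_ITER + 1):
        comp, total = _mixture_logpdf(x, w, mu, sd)
        ll = float(total.sum())
        resp = np.exp(comp - total)  # responsibilities, shape (2, n)
        nk = resp.sum(axis=1)
        w = nk / x.size
        mu = (resp @ x) / nk
        var = np.array([(resp[k] @ (x - mu[k]) ** 2) / nk[k] for k in range(2)])
        sd = np.sqrt(var)
        if np.any(sd < _SD_FLOOR):
            raise PermdegError(
                "mixture component collapsed (sd under floor); "
                "input may be unimodal or degenerate"
            )
        if trace and abs(ll - trace[-1]) <= _EM_TOL * abs(trace[-1]):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)

    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    threshold = equal_density_threshold(w, mu, sd)
    return GmmFit(
        weights=(float(w[0]), float(w[1])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        log_likelihood=trace[-1],
        n_iter=n_iter,
        converged=converged,
        threshold=threshold,
        ll_trace=trace,
    )


def select_expressed(matrix: ExpressionMatrix, threshold: float) -> ExpressionMatrix:
    """Keep genes with intensity strictly above ``threshold`` in >=1 sample."""
    if not np.isfinite(threshold) and not threshold == -np.inf:
        raise PermdegError("threshold must be finite or -inf")
    mask = (matrix.values.to_numpy(dtype=float) > threshold).any(axis=1)
    if not mask.any():
        raise PermdegError(
            f"no genes exceed the expression threshold {threshold!r}; "
            "review the gate before continuing"
        )
    return ExpressionMatrix(matrix.values.loc[mask].copy(), dict(matrix.design))
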