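"""Normalization and mixture-gating behaviour against hand and grid oracles."""

import numpy as np
import pandas as pd
import pytest

from permdeg import (
    ExpressionMatrix,
    PermdegError,
    equal_density_threshold,
    fit_expression_gmm,
    log2_transform,
    quantile_normalize,
    select_expressed,
)


def _mat(cols: dict, design=None):
    frame = pd.DataFrame(cols)
    frame.index = [f"g{i}" for i in range(len(frame))]
    design = design or {c: "G" for c in frame.columns}
    return ExpressionMatrix(frame, design)


# --- log2 -------------------------------------------------------------------


def test_log2_known_values():
    m = _mat({"s1": [1.0, 8.0], "s2": [2.0, 4.0]})
    out = log2_transform(m)
    assert out.values.to_numpy().tolist() == [[0.0, 1.0], [3.0, 2.0]]


def test_log2_all_ones_gives_zeros():
    m = _mat({"s1": [1.0, 1.0], "s2": [1.0, 1.0]})
    assert (log2_transform(m).values.to_numpy() == 0).all()


def test_log2_rejects_nonpositive_naming_coordinates():
    m = _mat({"s1": [1.0, 0.0], "s2": [2.0, 4.0]})
    with pytest.raises(PermdegError, match="g1.*s1"):
        log2_transform(m)


# --- quantile normalization -------------------------------------------------


def test_quantile_normalize_hand_oracle():
    """Two samples (2,4,6) and (3,5,7) -> both (2.5,4.5,6.5) in rank order."""
    m = _mat({"s1": [2.0, 4.0, 6.0], "s2": [7.0, 3.0, 5.0]})
    out = quantile_normalize(m).values
    assert out["s1"].tolist() == [2.5, 4.5, 6.5]
    assert out["s2"].tolist() == [6.5, 2.5, 4.5]


def test_quantile_normalize_identical_columns_unchanged():
    m = _mat({"s1": [1.0, 5.0, 9.0], "s2": [1.0, 5.0, 9.0]})
    assert np.allclose(quantile_normalize(m).values, m.values)


def test_quantile_normalize_single_gene_gets_row_mean():
    m = _mat({"s1": [4.0], "s2": [8.0]})
    assert np.allclose(quantile_normalize(m).values.to_numpy(), 6.0)


def test_quantile_normalize_tie_handling():
    """Tied values receive the mean reference value of their rank positions."""
    m = _mat({"s1": [1.0, 1.0, 10.0], "s2": [2.0, 4.0, 6.0]})
    out = quantile_normalize(m).values
    ref = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)  # [1.5, 2.5, 8.0]
    assert out["s1"].tolist() == [(ref[0] + ref[1]) / 2, (ref[0] + ref[1]) / 2, ref[2]]
    assert out["s2"].tolist() == ref.tolist()


def test_quantile_normalize_idempotent_and_common_multiset():
    rng = np.random.default_rng(0)
    m = _mat({f"s{j}": rng.normal(5, 2, 40) for j in range(4)})
    once = quantile_normalize(m)
    twice = quantile_normalize(once)
    assert np.allclose(once.values, twice.values, atol=1e-9)
    arr = once.values.to_numpy()
    ref = np.sort(arr[:, 0])
    for j in range(arr.shape[1]):
        assert np.allclose(np.sort(arr[:, j]), ref)


def test_quantile_normalize_rejects_missing_values():
    frame = pd.DataFrame({"s1": [1.0, np.nan], "s2": [2.0, 3.0]}, index=["g0", "g1"])
    with pytest.raises(PermdegError):
        # the container itself refuses non-finite input
        ExpressionMatrix(frame, {"s1": "G", "s2": "G"})


def test_quantile_normalize_needs_two_samples():
    with pytest.raises(PermdegError):
        quantile_normalize(_mat({"s1": [1.0, 2.0]}))


# --- expression mixture -----------------------------------------------------


@pytest.fixture(scope="module")
def mixture_sample():
    rng = np.random.default_rng(123)
    comp = rng.random(10_000) < 0.5
    x = np.where(comp, rng.normal(8, 1.0, 10_000), rng.normal(3, 0.5, 10_000))
    return x


def test_gmm_recovers_mixture_and_threshold(mixture_sample):
    """Means within 0.1 and threshold within 0.1 of the grid-search crossing."""
    fit = fit_expression_gmm(mixture_sample, seed=0)
    assert abs(fit.means[0] - 3.0) < 0.1
    assert abs(fit.means[1] - 8.0) < 0.1
    assert 0.45 < fit.weights[0] < 0.55
    # independent brute-force density grid for the analytic crossing
    from scipy.stats import norm

    grid = np.linspace(3, 8, 100_001)
    diff = 0.5 * norm.pdf(grid, 3, 0.5) - 0.5 * norm.pdf(grid, 8, 1.0)
    crossing = grid[np.argmin(np.abs(diff))]
    assert abs(fit.threshold - crossing) < 0.1


def test_gmm_loglik_nondecreasing(mixture_sample):
    fit = fit_expression_gmm(mixture_sample)
    trace = np.array(fit.ll_trace)
    assert np.all(np.diff(trace) >= -1e-8 * np.abs(trace[:-1]))
    assert fit.converged


def test_gmm_agrees_with_sklearn(mixture_sample):
    """Independent EM implementation reaches the same component means."""
    sklearn = pytest.importorskip("sklearn.mixture")
    gm = sklearn.GaussianMixture(2, random_state=0, n_init=3).fit(
        mixture_sample.reshape(-1, 1)
    )
    ref_means = np.sort(gm.means_.ravel())
    fit = fit_expression_gmm(mixture_sample)
    assert np.allclose(fit.means, ref_means, atol=0.05)


def test_gmm_threshold_reported_to_four_decimals(mixture_sample):
    fit = fit_expression_gmm(mixture_sample)
    rendered = fit.to_dict()["threshold_4dp"]
    assert rendered == f"{fit.threshold:.4f}"
    assert len(rendered.split(".")[1]) == 4


def test_gmm_degenerate_input_rejected():
    with pytest.raises(PermdegError):
        fit_expression_gmm(np.full(500, 6.0))


def test_gmm_too_few_values_rejected():
    with pytest.raises(PermdegError):
        fit_expression_gmm(np.arange(50, dtype=float))


def test_equal_density_threshold_symmetric_case():
    """Equal weights and sds -> the crossing is the midpoint of the means."""
    thr = equal_density_threshold((0.5, 0.5), (2.0, 6.0), (1.0, 1.0))
    assert thr == pytest.approx(4.0, abs=1e-6)


# --- expressed-gene selection -----------------------------------------------


def test_select_expressed_above_threshold_in_one_sample():
    m = _mat({"s1": [4.0, 2.0], "s2": [5.0, 3.0]})
    out = select_expressed(m, 4.8835)
    assert out.gene_ids == ["g0"]  # (4.0, 5.0) retained, (2.0, 3.0) dropped


def test_select_expressed_strictly_greater():
    m = _mat({"s1": [4.0, 5.0], "s2": [4.0, 6.0]})
    out = select_expressed(m, 4.0)
    assert out.gene_ids == ["g1"]


def test_select_expressed_minus_inf_keeps_all():
    m = _mat({"s1": [4.0, 2.0], "s2": [5.0, 3.0]})
    assert select_expressed(m, -np.inf).gene_ids == ["g0", "g1"]


def test_select_expressed_empty_result_errors():
    m = _mat({"s1": [1.0], "s2": [2.0]})
    with pytest.raises(PermdegError, match="threshold"):
        select_expressed(m, 10.0)


def test_select_expressed_monotone_in_threshold():
    rng = np.random.default_rng(5)
    m = _mat({f"s{j}": rng.normal(5, 2, 30) for j in range(3)})
    kept = [set(select_expressed(m, thr).gene_ids) for thr in (2.0, 4.0, 6.0)]
    assert kept[2] <= kept[1] <= kept[0]
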