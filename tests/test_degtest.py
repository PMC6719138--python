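"""Testing machinery against textbook formulas and brute-force enumeration."""

import numpy as np
import pytest
from scipy import stats

from permdeg import (
    Contrast,
    ExpressionMatrix,
    PermdegError,
    SimConfig,
    balanced_relabelings,
    build_null,
    call_degs,
    combine_pvalues,
    empirical_p,
    fc_cutoff,
    median_difference,
    simulate_null_matrix,
    t_statistic,
    test_contrast,
)


# --- elementary statistics --------------------------------------------------


def test_t_statistic_textbook_oracle():
    t, p = t_statistic([1, 2], [3, 4])
    assert t == pytest.approx(-2.8284, abs=1e-4)
    assert p == pytest.approx(0.1056, abs=1e-4)
    # independent route: scipy's pooled-variance t
    ref = stats.ttest_ind([1, 2], [3, 4], equal_var=True)
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_t_statistic_identical_groups():
    assert t_statistic([1, 2], [1, 2]) == (0.0, pytest.approx(1.0))


def test_t_statistic_constant_unequal_groups_sentinel():
    t, p = t_statistic([2, 2], [1, 1])
    assert t == np.inf and p == 0.0
    t, p = t_statistic([1, 1], [2, 2])
    assert t == -np.inf and p == 0.0


def test_t_statistic_rejects_single_value_group():
    with pytest.raises(PermdegError):
        t_statistic([1], [2, 3, 4])


def test_median_difference_hand_oracle():
    assert median_difference([1, 3], [2, 6]) == -2.0
    assert median_difference([3, 1], [6, 2]) == -2.0  # order invariance
    assert median_difference([5, 5], [5, 5]) == 0.0


def test_empirical_p_direct_count_oracle():
    assert empirical_p(2.5, [1, 2, 3, 4]) == pytest.approx(0.6)  # (2+1)/5
    assert empirical_p(0.0, [1, 2, 3, 4]) == 1.0
    assert empirical_p(99.0, [1, 2, 3, 4]) == pytest.approx(1 / 5)


def test_empirical_p_one_sided():
    assert empirical_p(2.5, [1, 2, 3, 4], two_sided=False) == pytest.approx(0.6)
    assert empirical_p(-10.0, [1, 2, 3, 4], two_sided=False) == 1.0


def test_combine_pvalues_normal_quantile_oracle():
    z, p = combine_pvalues(0.05, 0.05)
    assert z == pytest.approx(2.3262, abs=1e-4)
    assert p == pytest.approx(0.0100, abs=1e-4)


@pytest.mark.parametrize("pa", [0.2, 0.5, 0.9])
def test_combine_pvalues_symmetry_and_cancellation(pa):
    assert combine_pvalues(pa, 1 - pa)[1] == pytest.approx(0.5)
    assert combine_pvalues(0.5, 0.5)[1] == pytest.approx(0.5)


def test_combine_pvalues_fisher_switch():
    z_s, p_s = combine_pvalues(0.01, 0.02, method="stouffer")
    z_f, p_f = combine_pvalues(0.01, 0.02, method="fisher")
    ref = stats.combine_pvalues([0.01, 0.02], method="fisher").pvalue
    assert p_f == pytest.approx(ref, rel=1e-9)
    assert 0 < p_s < 0.05 and 0 < p_f < 0.05
    with pytest.raises(PermdegError):
        combine_pvalues(0.1, 0.1, method="bogus")


# --- permutation scheme -----------------------------------------------------


def test_balanced_relabelings_2v2():
    """Unordered balanced partitions minus identity: C(3,1)-1 = 2 for 2v2."""
    relabs = balanced_relabelings(2, 2)
    assert sorted(relabs) == [(0, 2), (0, 3)]


def test_balanced_relabelings_unequal_sizes():
    relabs = balanced_relabelings(2, 3)
    assert len(relabs) == 9  # C(5,2) - identity
    assert (0, 1) not in relabs


def test_build_null_sizes_and_determinism(toy_2v2):
    contrast = Contrast("KD", "WT")
    null1 = build_null(toy_2v2, contrast, seed=0)
    null2 = build_null(toy_2v2, contrast, seed=0)
    assert null1.scheme == "exhaustive:2"
    for name in ("null_t", "null_md", "null_log2fc", "null_combined_z"):
        arr1, arr2 = getattr(null1, name), getattr(null2, name)
        assert arr1.shape == (3 * 2,)  # n_genes x n_relabelings
        assert np.array_equal(arr1, arr2)


def test_build_null_zero_noise_null_matrix_all_zero():
    m, _ = simulate_null_matrix(
        SimConfig(
            n_genes=30, groups=("WT", "KD1"), replicate_sd=0.0,
            spike_table=[], seed=2,
        )
    )
    null = build_null(m, Contrast("KD1", "WT"))
    assert np.all(null.null_t == 0.0)
    assert np.all(null.null_md == 0.0)
    assert np.all(null.null_log2fc == 0.0)


def test_brute_force_oracle_equivalence(toy_2v2):
    """Every statistic matches a from-scratch recomputation on the toy matrix.

    The two balanced non-identity partitions of samples (a1,a2,b1,b2) are
    {a1,b1 | a2,b2} and {a1,b2 | a2,b1}; all statistics and empirical
    p-values are recomputed here with plain Python and must agree exactly.
    """
    contrast = Contrast("KD", "WT")
    result = test_contrast(toy_2v2, contrast, seed=0)
    vals = toy_2v2.values

    def pooled_t(a, b):
        ma, mb = np.mean(a), np.mean(b)
        ss = sum((x - ma) ** 2 for x in a) + sum((x - mb) ** 2 for x in b)
        se = np.sqrt(ss / 2 * (1 / 2 + 1 / 2))
        return (ma - mb) / se

    # observed per-gene statistics
    for gene in vals.index:
        a = [vals.loc[gene, "KD_1"], vals.loc[gene, "KD_2"]]
        b = [vals.loc[gene, "WT_1"], vals.loc[gene, "WT_2"]]
        assert result.stats.loc[gene, "t_stat"] == pytest.approx(pooled_t(a, b), abs=1e-12)
        assert result.stats.loc[gene, "median_diff"] == pytest.approx(
            np.median(a) - np.median(b), abs=1e-12
        )
        assert result.stats.loc[gene, "log2fc"] == pytest.approx(
            np.mean(a) - np.mean(b), abs=1e-12
        )

    # brute-force null: relabelings listed by hand
    order = ["KD_1", "KD_2", "WT_1", "WT_2"]
    null_md, null_fc, null_t = [], [], []
    for test_set in [("KD_1", "WT_1"), ("KD_1", "WT_2")]:
        ref_set = [s for s in order if s not in test_set]
        for gene in vals.index:
            a = [vals.loc[gene, s] for s in test_set]
            b = [vals.loc[gene, s] for s in ref_set]
            null_t.append(pooled_t(a, b))
            null_md.append(np.median(a) - np.median(b))
            null_fc.append(np.mean(a) - np.mean(b))
    assert sorted(null_md) == pytest.approx(sorted(result.null.null_md), abs=1e-12)
    assert sorted(null_fc) == pytest.approx(sorted(result.null.null_log2fc), abs=1e-12)
    assert sorted(null_t) == pytest.approx(sorted(result.null.null_t), abs=1e-12)

    # empirical p of each gene's median difference over the pooled null
    for gene in vals.index:
        md = result.stats.loc[gene, "median_diff"]
        count = sum(abs(x) >= abs(md) for x in null_md)
        assert result.stats.loc[gene, "p_md"] == pytest.approx(
            (count + 1) / (len(null_md) + 1), abs=1e-12
        )


def test_swap_symmetry(random_matrix):
    """Swapping test and reference negates fc and md, preserves adjusted p."""
    fwd = test_contrast(random_matrix, Contrast("grpA", "grpB"), seed=1)
    rev = test_contrast(random_matrix, Contrast("grpB", "grpA"), seed=1)
    assert np.allclose(fwd.stats["log2fc"], -rev.stats["log2fc"])
    assert np.allclose(fwd.stats["median_diff"], -rev.stats["median_diff"])
    assert np.allclose(fwd.stats["adjusted_p"], rev.stats["adjusted_p"])
    assert fwd.fc_cutoff == pytest.approx(rev.fc_cutoff)


def test_equal_combined_z_equal_adjusted_p(random_matrix):
    res = test_contrast(random_matrix, Contrast("grpA", "grpB"), seed=0)
    z = res.stats["combined_z"].round(12)
    grouped = res.stats.groupby(z)["adjusted_p"].nunique()
    assert (grouped == 1).all()


# --- cutoff and calling -----------------------------------------------------


def test_fc_cutoff_folded_normal_oracle():
    """95% of |N(0, 0.25^2)| is 1.96 x 0.25 ~ 0.49."""
    rng = np.random.default_rng(0)
    null = rng.normal(0, 0.25, 100_000)
    assert fc_cutoff(null, 0.95) == pytest.approx(0.49, abs=0.01)


def test_fc_cutoff_zeros_and_validation():
    assert fc_cutoff(np.zeros(10)) == 0.0
    with pytest.raises(PermdegError):
        fc_cutoff([])
    with pytest.raises(PermdegError):
        fc_cutoff([1.0], level=1.5)


def test_call_degs_strict_thresholds(random_matrix):
    import pandas as pd

    table = pd.DataFrame(
        {
            "adjusted_p": [0.01, 0.2, 0.01, 0.049],
            "log2fc": [0.6, 3.0, 0.4428, -0.5],
        },
        index=["up_gene", "ns_gene", "boundary_gene", "down_gene"],
    )
    degs = call_degs(table, Contrast("KD", "WT"), alpha=0.05, cutoff=0.4428)
    assert degs.genes == {"up_gene": "up", "down_gene": "down"}


def test_call_degs_monotone_in_alpha_and_cutoff(random_matrix):
    res = test_contrast(random_matrix, Contrast("grpA", "grpB"), seed=0)
    base = set(call_degs(res.stats, res.contrast, 0.5, 0.0).genes)
    stricter_alpha = set(call_degs(res.stats, res.contrast, 0.1, 0.0).genes)
    stricter_cutoff = set(call_degs(res.stats, res.contrast, 0.5, 1.0).genes)
    assert stricter_alpha <= base
    assert stricter_cutoff <= base


def test_test_contrast_needs_two_replicates():
    import pandas as pd

    frame = pd.DataFrame(
        {"A_1": [1.0, 2.0], "B_1": [2.0, 3.0], "B_2": [2.0, 3.0]},
        index=["g0", "g1"],
    )
    m = ExpressionMatrix(frame, {"A_1": "A", "B_1": "B", "B_2": "B"})
    with pytest.raises(PermdegError):
        test_contrast(m, Contrast("A", "B"))


def test_contrast_requires_distinct_groups():
    with pytest.raises(PermdegError):
        Contrast("WT", "WT")
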