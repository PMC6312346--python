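"""Cross-species correlation, clustering and ALT conservation counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from mztevo.comparative import (
    alt_conservation_count,
    correlation_matrix,
    hierarchical_cluster,
    pairwise_category_correlation,
    shared_stage_restricted_counts,
    spearman,
    top_split,
)


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        # rank formula: 1 - 6*sum(d^2)/(n(n^2-1)) with sum(d^2) = 6
        ([1, 2, 3], [3, 1, 2], -0.5),
    ],
)
def test_spearman_worked_values(x, y, expected):
    assert spearman(x, y) == pytest.approx(expected, abs=1e-12)


def test_spearman_constant_vector_is_undefined():
    assert spearman([1, 1, 1], [1, 2, 3]) is None


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.integers(1, 10**6), min_size=4, max_size=20, unique=True))
def test_spearman_invariant_under_monotone_transforms(vals):
    xs = np.asarray(vals, dtype=float)
    rng = np.random.default_rng(42)
    ys = rng.permutation(xs)
    base = spearman(xs, ys)
    assert spearman(np.log(xs), ys) == pytest.approx(base, abs=1e-9)
    assert spearman(xs**3, ys) == pytest.approx(base, abs=1e-9)
    assert spearman(3.5 * xs + 2, ys) == pytest.approx(base, abs=1e-9)


def _species_frame(rng, n, category_mask, means5):
    cat = np.where(category_mask, "Z", "MZ")
    return pd.DataFrame(
        {
            "s2_mean": rng.uniform(1, 50, n),
            "s5_mean": means5,
            "category": cat,
        },
        index=[f"g{i}" for i in range(n)],
    )


def test_pairwise_modes_and_subset_relation():
    rng = np.random.default_rng(5)
    n = 120
    conserved = np.arange(n) < 40  # zygotic-only in both species, correlated
    either = (np.arange(n) >= 40) & (np.arange(n) < 70)  # category in A only
    base = rng.uniform(2, 100, n)
    a = _species_frame(rng, n, conserved | either, base)
    b = _species_frame(
        rng, n, conserved, np.where(conserved, base * rng.lognormal(0, 0.1, n), rng.uniform(2, 100, n))
    )
    both = pairwise_category_correlation(a, b, "zygotic_only", "shared_in_both")
    any_ = pairwise_category_correlation(a, b, "zygotic_only", "in_either")
    assert both.n_genes <= any_.n_genes
    assert both.n_genes == 40 and any_.n_genes == 70
    assert both.rho > any_.rho  # conserved subset correlates better
    same = pairwise_category_correlation(a, a, "zygotic_only", "shared_in_both")
    assert same.rho == pytest.approx(1.0)


def test_pairwise_too_few_genes_gives_absent_rho():
    a = pd.DataFrame({"s2_mean": [5.0], "s5_mean": [0.1], "category": ["M"]}, index=["g0"])
    res = pairwise_category_correlation(a, a, "maternal_only")
    assert res.rho is None and res.n_genes == 1


def test_correlation_matrix_properties():
    rng = np.random.default_rng(1)
    base = rng.lognormal(3, 1, 300)
    cond = pd.DataFrame(
        {
            "a|stage2": base * rng.lognormal(0, 0.1, 300),
            "b|stage2": base * rng.lognormal(0, 0.1, 300),
            "a|stage5": base[::-1] * rng.lognormal(0, 0.1, 300),
            "b|stage5": base[::-1] * rng.lognormal(0, 0.1, 300),
        }
    )
    corr = correlation_matrix(cond)
    np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)
    np.testing.assert_allclose(np.diag(corr), 1.0)
    # within-stage correlation exceeds between-stage for every pair
    for s in ("stage2", "stage5"):
        within = corr.loc[f"a|{s}", f"b|{s}"]
        for t in ("stage2", "stage5"):
            if t != s:
                assert within > corr.loc[f"a|{s}", f"b|{t}"]
    # subsetting then recomputing agrees with the submatrix
    sub = correlation_matrix(cond[["a|stage2", "b|stage2"]])
    assert sub.loc["a|stage2", "b|stage2"] == pytest.approx(
        corr.loc["a|stage2", "b|stage2"], abs=1e-12
    )


def test_identical_conditions_give_unit_matrix():
    cond = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [1.0, 2, 3, 4]})
    corr = correlation_matrix(cond)
    np.testing.assert_allclose(corr.to_numpy(), 1.0)


def test_cluster_top_split_separates_blocks(noisy_sim):
    """Stage-specific expression blocks make stages the first split."""
    rng = np.random.default_rng(2)
    n = 400
    sig2 = rng.lognormal(3, 1, n)
    sig5 = rng.lognormal(3, 1, n)
    cols = {}
    for sp in "abcdef":
        cols[f"{sp}|stage2"] = sig2 * rng.lognormal(0, 0.3, n)
        cols[f"{sp}|stage5"] = sig5 * rng.lognormal(0, 0.3, n)
    corr = correlation_matrix(pd.DataFrame(cols))
    clustering = hierarchical_cluster(corr)
    left, right = top_split(clustering)
    stages = {frozenset(lbl.split("|")[1] for lbl in side) for side in (left, right)}
    assert stages == {frozenset({"stage2"}), frozenset({"stage5"})}


def test_cluster_label_equivariance():
    rng = np.random.default_rng(3)
    m = rng.uniform(0.3, 0.9, (5, 5))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    labels = list("vwxyz")
    corr = pd.DataFrame(m, index=labels, columns=labels)
    perm = ["x", "z", "v", "w", "y"]
    orig = hierarchical_cluster(corr)
    permuted = hierarchical_cluster(corr.loc[perm, perm])
    def leaf_sets(clus):
        a, b = top_split(clus)
        return {frozenset(a), frozenset(b)}
    assert leaf_sets(orig) == leaf_sets(permuted)


def test_cluster_rejects_asymmetric_input():
    bad = pd.DataFrame([[1.0, 0.5], [0.2, 1.0]], index=["a", "b"], columns=["a", "b"])
    with pytest.raises(ValueError, match="symmetric"):
        hierarchical_cluster(bad)


def test_rho_decreases_with_patristic_distance(noisy_sim):
    """Tree-structured divergence: closer species correlate more strongly."""
    from mztevo.io import ortholog_matrix

    ds = noisy_sim
    conditions = ds.conditions()
    mat = ortholog_matrix(conditions, ds.orthologs, "stage2").dropna()
    dist = ds.tree.patristic_distances()
    tips = ds.tree.tip_labels
    rhos, dists = [], []
    focal = "mel"
    i = tips.index(focal)
    for j, sp in enumerate(tips):
        if sp == focal:
            continue
        rhos.append(spearman(mat[focal], mat[sp]))
        dists.append(dist[i, j])
    rank_corr = spearmanr(rhos, dists).statistic
    assert rank_corr < 0


def test_alt_conservation_count():
    flags = pd.DataFrame(
        {
            "s1": [True, False, True],
            "s2": [True, False, np.nan],
            "s3": [True, False, True],
        },
        index=["ga", "gb", "gc"],
    )
    out = alt_conservation_count(flags)
    assert out.loc["ga", "n_alt"] == 3 and out.loc["ga", "conserved"]
    assert out.loc["gb", "n_alt"] == 0 and not out.loc["gb", "conserved"]
    assert out.loc["gc", "n_alt"] == 2  # ceil(2/3 * 3) = 2
    shuffled = alt_conservation_count(flags[["s3", "s1", "s2"]])
    pd.testing.assert_series_equal(out["n_alt"], shuffled["n_alt"])


def test_shared_stage_restricted_counts():
    a = pd.Series(["M", "M", "Z", "Z", "MZ"], index=list("abcde"))
    b = pd.Series(["M", "Z", "Z", "MZ", "MZ"], index=list("abcde"))
    n_m, n_z = shared_stage_restricted_counts(a, b)
    assert (n_m, n_z) == (1, 1)
    assert shared_stage_restricted_counts(a, a) == (2, 2)
    assert n_m <= min((a == "M").sum(), (b == "M").sum())
    disjoint = pd.Series(["Z", "Z", "M", "M", "N"], index=list("abcde"))
    assert shared_stage_restricted_counts(a, disjoint) == (0, 0)
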