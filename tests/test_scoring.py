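import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import oracles
from debrisem import scoring


def test_debris_cluster_rule_boundary_and_fixed_cluster():
    assignments = np.array([0, 0, 1, 1, 2, 2])
    genes = np.array([500, 500, 199, 200, 200, 200])
    debris = scoring.define_debris_clusters(assignments, genes, d=200)
    assert debris == {0, 1}  # cluster 1 mean is 199.5 < 200; cluster 2 mean is 200
    assert scoring.define_debris_clusters(assignments, genes, d=0) == {0}


def test_all_debris_clusters_is_an_error():
    with pytest.raises(ValueError, match="no cell-type clusters"):
        scoring.define_debris_clusters(np.array([0, 1]), np.array([10, 10]), d=200)


def test_normalize_for_de_proportions_then_log1p():
    norm = scoring.normalize_for_de(sp.csr_matrix(np.array([[2, 0], [2, 5]])))
    dense = norm.toarray()
    assert dense[0, 0] == pytest.approx(np.log(1.5))
    assert dense[1, 0] == pytest.approx(np.log(1.5))
    assert dense[0, 1] == 0.0


def test_normalize_for_de_invariant_to_droplet_scaling():
    x = np.array([[3, 9], [5, 15], [0, 0]])
    norm = scoring.normalize_for_de(sp.csr_matrix(x))
    assert np.allclose(norm.toarray()[:, 0], norm.toarray()[:, 1])


def test_welch_de_matches_brute_force_on_five_vs_five():
    rng = np.random.default_rng(0)
    a = rng.normal(1.0, 0.5, size=(4, 5))
    b = rng.normal(0.5, 1.5, size=(4, 5))
    norm = sp.csr_matrix(np.hstack([a, b]))
    tab = scoring.debris_de(norm, np.arange(5), np.arange(5, 10), list("wxyz"))
    for i in range(4):
        t, df, p = oracles.welch_t(a[i], b[i])
        assert tab["t_statistic"].iloc[i] == pytest.approx(t, abs=1e-10)
        assert tab["p_value"].iloc[i] == pytest.approx(p, abs=1e-10)
        assert tab["log_fold_change"].iloc[i] == pytest.approx(
            a[i].mean() - b[i].mean(), abs=1e-12
        )
    q = oracles.bh_qvalues(tab["p_value"].to_numpy())
    assert np.allclose(tab["q_value"], q, atol=1e-10)


def test_zero_variance_gene_gets_p_one():
    x = np.ones((1, 8))
    tab = scoring.debris_de(sp.csr_matrix(x), np.arange(4), np.arange(4, 8), ["g"])
    assert tab["p_value"].iloc[0] == 1.0
    assert not tab["enriched"].iloc[0]


def test_de_requires_two_droplets_per_group():
    with pytest.raises(ValueError, match="at least 2"):
        scoring.debris_de(sp.csr_matrix(np.ones((2, 3))), [0], [1, 2], ["a", "b"])


def test_enriched_needs_positive_lfc():
    # a gene higher in the cell-type group can be significant but never enriched
    a = np.zeros((1, 10))
    b = np.ones((1, 10)) + np.linspace(0, 0.01, 10)
    tab = scoring.debris_de(
        sp.csr_matrix(np.hstack([a, b])), np.arange(10), np.arange(10, 20), ["g"]
    )
    assert tab["log_fold_change"].iloc[0] < 0
    assert not tab["enriched"].iloc[0]


def test_score_droplets_sums_enriched_gene_expression():
    norm = sp.csr_matrix(np.array([[0.5, 0.0], [0.2, 0.0], [0.9, 0.3]]))
    raw = scoring.score_droplets(norm, [0, 2])
    assert raw == pytest.approx([1.4, 0.3])
    # droplet expressing none of the enriched genes scores 0
    assert scoring.score_droplets(norm, [1])[1] == 0.0
    # adding an enriched gene with positive expression raises the score
    more = scoring.score_droplets(norm, [0, 1, 2])
    assert np.all(more >= raw)


def test_empty_enriched_set_is_an_error():
    with pytest.raises(ValueError, match="no debris-enriched genes"):
        scoring.score_droplets(sp.csr_matrix(np.ones((2, 2))), [])


def test_score_normalization_anchor_points_and_midway():
    raw = np.array([0.0, 0.0, 10.0, 10.0, 5.0])
    clusters = np.array([1, 1, 0, 0, 2])
    norm = scoring.normalize_scores(raw, clusters, {0})
    assert norm[:2].tolist() == [0.0, 0.0]
    assert norm[2:4].tolist() == [1.0, 1.0]
    assert norm[4] == pytest.approx(0.5)


def test_score_normalization_affine_invariance():
    rng = np.random.default_rng(1)
    raw = rng.normal(size=30)
    clusters = rng.integers(0, 3, size=30)
    raw[clusters == 0] += 5  # make debris clearly elevated
    a = scoring.normalize_scores(raw, clusters, {0})
    b = scoring.normalize_scores(3.5 * raw - 2.0, clusters, {0})
    assert np.allclose(a, b, atol=1e-12)


def test_flat_debris_scores_are_an_error():
    raw = np.array([5.0, 5.0, 1.0, 1.0])
    clusters = np.array([1, 1, 0, 0])
    with pytest.raises(ValueError, match="elevated"):
        scoring.normalize_scores(raw, clusters, {0})


def test_literal_normalization_variant():
    raw = np.array([2.0, 2.0, 10.0, 10.0])
    clusters = np.array([1, 1, 0, 0])
    norm = scoring.normalize_scores(raw, clusters, {0}, mode="literal")
    assert np.allclose(norm, (raw - 2.0) / 10.0)


def _score_table(scores, clusters, membership):
    return pd.DataFrame(
        {
            "normalized_score": scores,
            "cluster": clusters,
            "set_membership": membership,
        }
    )


def test_filtering_monotone_in_cutoff_and_removes_fixed():
    tab = _score_table(
        [0.1, 0.4, 0.6, 0.2], [1, 1, 0, 0], ["test", "test", "test", "fixed_debris"]
    )
    kept_sets = []
    for t in (0.0, 0.3, 0.5, 1.0, np.inf):
        keep = scoring.filter_droplets(tab, t=t)
        assert not keep[3]  # fixed droplets always removed
        kept_sets.append(set(np.flatnonzero(keep)))
    for small, big in zip(kept_sets, kept_sets[1:]):
        assert small <= big
    assert kept_sets[-1] == {0, 1, 2}  # t -> inf keeps the whole test set


def test_cluster_mode_keeps_non_debris_clusters():
    tab = _score_table([0.9, 0.1, 0.1], [0, 2, 1], ["test", "test", "fixed_debris"])
    keep = scoring.filter_droplets(tab, mode="cluster", debris_clusters={0, 1})
    assert keep.tolist() == [False, True, False]


def test_bh_implementation_matches_step_up_oracle_on_random_pvalues():
    rng = np.random.default_rng(2)
    from statsmodels.stats.multitest import multipletests

    for _ in range(20):
        p = rng.uniform(size=rng.integers(1, 40))
        ours = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, oracles.bh_qvalues(p), atol=1e-12)
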