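import numpy as np
import pytest
import scipy.sparse as sp

import oracles
from debrisem import em


def random_instance(seed, max_g=20, max_n=200, max_k=4):
    """A random mixture instance: counts, init params, fixed mask."""
    rng = np.random.default_rng(seed)
    g = rng.integers(3, max_g + 1)
    n = rng.integers(10, max_n + 1)
    k = rng.integers(1, max_k + 1)
    counts = rng.poisson(rng.uniform(0.2, 3.0), size=(g, n))
    counts[:, 0] += 1  # at least one nonzero droplet
    alpha = rng.dirichlet(np.ones(g), size=k + 1)
    pi = rng.dirichlet(np.ones(k + 1))
    params = em.MixtureParams(alpha=alpha, pi=pi)
    fixed = rng.random(n) < 0.3
    return sp.csc_matrix(counts), params, fixed


def test_multinomial_log_prob_single_draw():
    assert em.multinomial_log_prob([1, 0], [0.5, 0.5]) == pytest.approx(np.log(0.5))


def test_multinomial_log_prob_with_coefficient_matches_enumeration():
    got = em.multinomial_log_prob([2, 1], [2 / 3, 1 / 3], include_coefficient=True)
    assert got == pytest.approx(np.log(4 / 9), abs=1e-12)
    assert got == pytest.approx(
        np.log(oracles.multinomial_pmf([2, 1], [2 / 3, 1 / 3])), abs=1e-12
    )


def test_multinomial_log_prob_ignores_zero_count_genes():
    base = em.multinomial_log_prob([3, 1], [0.7, 0.3])
    padded = em.multinomial_log_prob([3, 1, 0], [0.7 * 0.9, 0.3 * 0.9, 0.1])
    # same counts on rescaled probabilities differ, but a zero count against
    # any alpha contributes nothing
    assert em.multinomial_log_prob([3, 1, 0], [0.7, 0.3, 0.0]) == pytest.approx(base)
    assert padded != pytest.approx(base)


def test_e_step_symmetric_components_give_uniform_posterior():
    counts = sp.csc_matrix(np.array([[3], [1]]))
    params = em.MixtureParams(alpha=[[0.5, 0.5], [0.5, 0.5]], pi=[0.5, 0.5])
    post = em.e_step(counts, params)
    assert np.allclose(post.probs, 0.5)


def test_e_step_fixed_droplets_are_one_hot_at_debris():
    counts = sp.csc_matrix(np.array([[30, 1], [1, 30]]))
    params = em.MixtureParams(alpha=[[0.1, 0.9], [0.9, 0.1]], pi=[0.5, 0.5])
    post = em.e_step(counts, params, fixed_mask=np.array([True, False]))
    assert post.probs[0].tolist() == [1.0, 0.0]
    assert post.probs[1].sum() == pytest.approx(1.0)


def test_e_step_matches_direct_bayes_oracle():
    x = [3, 1]
    alphas = [[0.9, 0.1], [0.1, 0.9]]
    pis = [0.4, 0.6]
    params = em.MixtureParams(alpha=alphas, pi=pis)
    post = em.e_step(sp.csc_matrix(np.array([x]).T), params)
    expect = oracles.bayes_posterior(x, alphas, pis)
    assert np.allclose(post.probs[0], expect, atol=1e-12)


def test_posteriors_invariant_to_multinomial_coefficient():
    # the coefficient depends on x only, so dividing every joint term by it
    # leaves the posterior unchanged; check against the coefficient-full oracle
    rng = np.random.default_rng(0)
    for _ in range(10):
        x = rng.integers(0, 6, size=4)
        if x.sum() == 0:
            continue
        alphas = rng.dirichlet(np.ones(4), size=3)
        pis = rng.dirichlet(np.ones(3))
        params = em.MixtureParams(alpha=alphas, pi=pis)
        post = em.e_step(sp.csc_matrix(x[:, None]), params)
        expect = oracles.bayes_posterior(x, alphas, pis)
        assert np.allclose(post.probs[0], expect, atol=1e-12)


def test_m_step_with_hard_posteriors_pools_cluster_counts():
    counts = sp.csc_matrix(np.array([[4, 0], [0, 6]]))
    probs = np.array([[1.0, 0.0], [0.0, 1.0]])
    params = em.m_step(counts, em.PosteriorMatrix(probs, np.zeros(2, bool)))
    assert np.allclose(params.alpha[0], [1, 0], atol=1e-9)
    assert np.allclose(params.alpha[1], [0, 1], atol=1e-9)
    assert np.allclose(params.pi, [0.5, 0.5])


def test_m_step_empty_component_becomes_uniform_with_warning(caplog):
    counts = sp.csc_matrix(np.array([[4], [2]]))
    probs = np.array([[1.0, 0.0]])
    with caplog.at_level("WARNING"):
        params = em.m_step(counts, em.PosteriorMatrix(probs, np.zeros(1, bool)))
    assert np.allclose(params.alpha[1], [0.5, 0.5])
    assert "posterior mass" in caplog.text


def test_em_fixed_point_barely_moves_after_convergence():
    counts, params, fixed = random_instance(3)
    res = em.run_em(counts, params, fixed, eps=1e-7, max_iter=2000)
    again = em.run_em(counts, res.params, fixed, eps=1e-7, max_iter=2)
    assert again.trace["max_param_change"].iloc[0] < 1e-6


def test_k1_no_fixed_converges_to_pooled_proportions():
    rng = np.random.default_rng(4)
    counts = rng.poisson(2.0, size=(10, 50))
    counts[:, 0] += 1
    init = em.MixtureParams(alpha=rng.dirichlet(np.ones(10))[None, :], pi=[1.0])
    res = em.run_em(sp.csc_matrix(counts), init, eps=1e-10, max_iter=50)
    pooled = counts.sum(axis=1) / counts.sum()
    assert np.allclose(res.params.alpha[0], pooled, atol=1e-8)


def test_em_invariant_to_droplet_permutation():
    counts, params, fixed = random_instance(5)
    res = em.run_em(counts, params, fixed, max_iter=40)
    perm = np.random.default_rng(6).permutation(counts.shape[1])
    res_p = em.run_em(counts[:, perm], params, fixed[perm], max_iter=40)
    assert np.allclose(res.params.alpha, res_p.params.alpha, atol=1e-12)
    assert np.allclose(res.posteriors.probs[perm], res_p.posteriors.probs, atol=1e-12)


def test_loglik_trace_is_nondecreasing_for_random_instances():
    for seed in range(12):
        counts, params, fixed = random_instance(100 + seed)
        res = em.run_em(counts, params, fixed, max_iter=30)
        ll = res.trace["log_likelihood"].to_numpy()
        drops = np.diff(ll) / np.maximum(np.abs(ll[:-1]), 1.0)
        assert drops.min() >= -1e-8


def test_fixed_posteriors_stay_one_hot_through_iterations():
    counts, params, fixed = random_instance(7)
    fixed[:3] = True
    for _ in range(8):
        post = em.e_step(counts, params, fixed)
        assert np.all(post.probs[fixed, 0] == 1.0)
        assert np.all(post.probs[fixed, 1:] == 0.0)
        params = em.m_step(counts, post)


def test_assign_clusters_argmax_and_tie_break():
    probs = np.array([[0.7, 0.3], [0.5, 0.5], [0.2, 0.8]])
    labels = em.assign_clusters(em.PosteriorMatrix(probs, np.zeros(3, bool)))
    assert labels.tolist() == [0, 0, 1]


def test_observed_loglik_single_droplet_single_component():
    counts = sp.csc_matrix(np.array([[3], [2]]))
    params = em.MixtureParams(alpha=[[0.6, 0.4]], pi=[1.0])
    got = em.observed_log_likelihood(counts, params)
    assert got == pytest.approx(em.multinomial_log_prob([3, 2], [0.6, 0.4]))


def test_observed_loglik_matches_brute_force_toy():
    counts = np.array([[1, 2, 0], [3, 0, 2]])
    alphas = np.array([[0.3, 0.7], [0.8, 0.2]])
    pis = np.array([0.25, 0.75])
    params = em.MixtureParams(alpha=alphas, pi=pis)
    got = em.observed_log_likelihood(sp.csc_matrix(counts), params)
    expect = oracles.mixture_loglik(counts.T, alphas, pis)
    assert got == pytest.approx(expect, abs=1e-12)
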