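"""Sequence likelihood, greedy search, MCMC and positional-variance tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ebmkit.ebm import (
    EventBasedModel,
    EventLikelihoodMatrix,
    fit_ebm,
    greedy_ascent,
    mcmc_sample,
    positional_variance,
    sequence_log_likelihood,
)

from conftest import brute_force_sequence_likelihood, random_likelihood_instance


# ------------------------------------------------------------ likelihood (Eq. form)
def test_two_event_hand_enumeration():
    """One subject, two events: the stage sum can be enumerated by hand."""
    L = EventLikelihoodMatrix(np.array([[0.9, 0.2]]), np.array([[0.1, 0.8]]))
    # sequence (0,1): (1/3)(0.1*0.8 + 0.9*0.8 + 0.9*0.2)
    assert np.isclose(np.exp(sequence_log_likelihood(L, [0, 1])), 0.98 / 3, rtol=1e-12)
    # sequence (1,0): (1/3)(0.1*0.8 + 0.1*0.2 + 0.9*0.2)
    assert np.isclose(np.exp(sequence_log_likelihood(L, [1, 0])), 0.28 / 3, rtol=1e-12)


def test_uniform_likelihood_identity():
    """With P(x|E) = P(x|not E) = c everywhere the stage sum collapses and
    log P(X|S) = N Z log c for every sequence."""
    n, z, c = 4, 5, 0.3
    L = EventLikelihoodMatrix(np.full((n, z), c), np.full((n, z), c))
    for seq in ([0, 1, 2, 3, 4], [4, 2, 0, 3, 1]):
        assert np.isclose(sequence_log_likelihood(L, seq), n * z * np.log(c), rtol=1e-12)


def test_matches_brute_force_enumeration():
    rng = np.random.default_rng(0)
    for _ in range(20):
        z = rng.integers(2, 7)
        p_e, p_ne = random_likelihood_instance(rng, rng.integers(1, 8), z)
        L = EventLikelihoodMatrix(p_e, p_ne)
        seq = rng.permutation(z)
        expected = brute_force_sequence_likelihood(p_e, p_ne, seq)
        assert np.isclose(sequence_log_likelihood(L, seq), expected, rtol=1e-9)


def test_relabeling_invariance():
    """Permuting event columns and the sequence consistently leaves the
    likelihood unchanged."""
    rng = np.random.default_rng(1)
    p_e, p_ne = random_likelihood_instance(rng, 6, 5)
    L = EventLikelihoodMatrix(p_e, p_ne)
    seq = rng.permutation(5)
    relabel = rng.permutation(5)
    inv = np.argsort(relabel)
    L2 = EventLikelihoodMatrix(p_e[:, relabel], p_ne[:, relabel])
    assert np.isclose(
        sequence_log_likelihood(L, seq),
        sequence_log_likelihood(L2, inv[seq]),
        rtol=1e-12,
    )


def test_duplicating_subjects_scales_log_likelihood_differences():
    rng = np.random.default_rng(2)
    p_e, p_ne = random_likelihood_instance(rng, 5, 4)
    L1 = EventLikelihoodMatrix(p_e, p_ne)
    L2 = EventLikelihoodMatrix(np.vstack([p_e, p_e]), np.vstack([p_ne, p_ne]))
    s_a, s_b = rng.permutation(4), rng.permutation(4)
    d1 = sequence_log_likelihood(L1, s_a) - sequence_log_likelihood(L1, s_b)
    d2 = sequence_log_likelihood(L2, s_a) - sequence_log_likelihood(L2, s_b)
    assert np.isclose(d2, 2 * d1, rtol=1e-9)


def test_sequence_validation_errors():
    L = EventLikelihoodMatrix(np.full((2, 3), 0.5), np.full((2, 3), 0.5))
    with pytest.raises(ValueError, match="permutation"):
        sequence_log_likelihood(L, [0, 1, 1])
    with pytest.raises(ValueError, match="positive|finite"):
        EventLikelihoodMatrix(np.array([[0.5, 0.0]]), np.array([[0.5, 0.5]]))
    with pytest.raises(ValueError, match="positive|finite"):
        EventLikelihoodMatrix(np.array([[0.5, np.inf]]), np.array([[0.5, 0.5]]))


# ----------------------------------------------------------------------- greedy
def test_greedy_finds_exhaustive_optimum_on_small_instances():
    rng = np.random.default_rng(3)
    for _ in range(10):
        p_e, p_ne = random_likelihood_instance(rng, 12, 5)
        L = EventLikelihoodMatrix(p_e, p_ne)
        best_ll = max(
            sequence_log_likelihood(L, perm)
            for perm in itertools.permutations(range(5))
        )
        _, ll, _ = greedy_ascent(L, n_init=10, seed=0)
        assert np.isclose(ll, best_ll, rtol=1e-9)


def test_greedy_fixed_point_at_optimum():
    rng = np.random.default_rng(4)
    p_e, p_ne = random_likelihood_instance(rng, 12, 5)
    L = EventLikelihoodMatrix(p_e, p_ne)
    seq, ll, _ = greedy_ascent(L, n_init=10, seed=0)
    seq2, ll2, _ = greedy_ascent(L, init_sequences=[seq])
    assert np.array_equal(seq2, seq)
    assert ll2 == ll


def test_greedy_terminates_on_flat_landscape():
    L = EventLikelihoodMatrix(np.full((3, 6), 0.4), np.full((3, 6), 0.4))
    seq, ll, _ = greedy_ascent(L, n_init=1, seed=0)
    assert sorted(seq.tolist()) == list(range(6))
    assert np.isclose(ll, 3 * 6 * np.log(0.4), rtol=1e-12)


# ------------------------------------------------------------------------ MCMC
def test_mcmc_is_deterministic_under_fixed_seed():
    rng = np.random.default_rng(5)
    p_e, p_ne = random_likelihood_instance(rng, 10, 6)
    L = EventLikelihoodMatrix(p_e, p_ne)
    runs = [mcmc_sample(L, np.arange(6), n_samples=800, burn_in=100, seed=42)
            for _ in range(2)]
    assert np.array_equal(runs[0][0], runs[1][0])
    assert np.array_equal(runs[0][1], runs[1][1])


def test_mcmc_recorded_likelihoods_consistent():
    rng = np.random.default_rng(6)
    p_e, p_ne = random_likelihood_instance(rng, 8, 5)
    L = EventLikelihoodMatrix(p_e, p_ne)
    samples, lls, ml_seq, ml_ll = mcmc_sample(L, np.arange(5), n_samples=400,
                                              burn_in=100, seed=1)
    for s, ll in zip(samples[::29], lls[::29]):
        assert np.isclose(sequence_log_likelihood(L, s), ll, rtol=1e-10)
    assert ml_ll >= lls.max()


def test_mcmc_concentrates_on_dominant_sequence():
    """A strongly informative instance: nearly all samples equal the ML
    ordering."""
    rng = np.random.default_rng(7)
    z, n = 5, 60
    truth = np.array([2, 0, 4, 1, 3])
    position = np.argsort(truth)
    stages = rng.integers(0, z + 1, n)
    happened = position[None, :] < stages[:, None]
    p_e = np.where(happened, 0.95, 0.05)
    p_ne = np.where(happened, 0.05, 0.95)
    L = EventLikelihoodMatrix(p_e, p_ne)
    seq, _, _ = greedy_ascent(L, n_init=5, seed=0)
    samples, _, _, _ = mcmc_sample(L, seq, n_samples=6000, burn_in=1000, seed=0)
    match = np.mean(np.all(samples == seq[None, :], axis=1))
    assert match >= 0.95


def test_mcmc_input_validation():
    L = EventLikelihoodMatrix(np.full((2, 3), 0.5), np.full((2, 3), 0.5))
    with pytest.raises(ValueError, match="exceed"):
        mcmc_sample(L, np.arange(3), n_samples=100, burn_in=100)
    with pytest.raises(ValueError, match="permutation"):
        mcmc_sample(L, np.array([0, 0, 1]), n_samples=200, burn_in=10)


# ------------------------------------------------------------ positional variance
def test_positional_variance_of_identical_samples_is_permutation_matrix():
    samples = np.tile([2, 0, 1], (7, 1))
    pvd = positional_variance(samples)
    expected = np.zeros((3, 3))
    expected[2, 0] = expected[0, 1] = expected[1, 2] = 1.0
    assert np.array_equal(pvd, expected)


def test_positional_variance_single_swap_halves_cells():
    pvd = positional_variance([[0, 1, 2], [1, 0, 2]])
    assert pvd[0, 0] == 0.5 and pvd[0, 1] == 0.5
    assert pvd[1, 0] == 0.5 and pvd[1, 1] == 0.5
    assert pvd[2, 2] == 1.0


def test_positional_variance_uniform_permutations_approach_uniform():
    rng = np.random.default_rng(8)
    z, n = 10, 100_000
    samples = np.argsort(rng.random((n, z)), axis=1)
    pvd = positional_variance(samples)
    assert np.abs(pvd - 1 / z).max() < 0.01


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.permutations(list(range(6))), min_size=1, max_size=20))
def test_positional_variance_doubly_stochastic(perms):
    pvd = positional_variance(np.array(perms))
    assert np.allclose(pvd.sum(axis=0), 1.0, atol=1e-9)
    assert np.allclose(pvd.sum(axis=1), 1.0, atol=1e-9)


def test_positional_variance_rejects_mixed_lengths():
    with pytest.raises(ValueError):
        positional_variance([[0, 1, 2], [0, 2, 1, 3]])


# ------------------------------------------------------------------- estimator
def test_fit_ebm_matches_exhaustive_search():
    rng = np.random.default_rng(9)
    for _ in range(5):
        z = int(rng.integers(3, 6))
        p_e, p_ne = random_likelihood_instance(rng, 15, z)
        L = EventLikelihoodMatrix(p_e, p_ne)
        best = max(
            itertools.permutations(range(z)),
            key=lambda perm: sequence_log_likelihood(L, perm),
        )
        result = fit_ebm(L, n_init=5, mcmc_iterations=2000, burn_in=500, seed=0)
        assert np.isclose(
            result.log_likelihood, sequence_log_likelihood(L, best), rtol=1e-9
        )


def test_noninformative_event_has_diffuse_position():
    """An event with identical distributions in both groups gets no stable
    position: its positional-variance row has no dominant entry."""
    rng = np.random.default_rng(10)
    z, n = 6, 50
    truth = np.arange(z)
    stages = rng.integers(0, z + 1, n)
    happened = truth[None, :] < stages[:, None]
    # moderate evidence so the swap chain can actually traverse the flat
    # direction created by the null event
    p_e = np.where(happened, 0.65, 0.35)
    p_ne = np.where(happened, 0.35, 0.65)
    p_e[:, 3] = p_ne[:, 3] = 0.5  # event 3 carries no information
    L = EventLikelihoodMatrix(p_e, p_ne)
    result = fit_ebm(L, n_init=5, mcmc_iterations=100_000, burn_in=10_000, seed=0)
    assert result.positional_variance[3].max() < 0.5


def test_estimator_follows_sklearn_conventions():
    from sklearn.base import clone

    model = EventBasedModel(n_init=3, mcmc_iterations=0, random_state=7)
    params = model.get_params()
    assert params["n_init"] == 3
    cloned = clone(model)
    rng = np.random.default_rng(11)
    p_e, p_ne = random_likelihood_instance(rng, 10, 4)
    L = EventLikelihoodMatrix(p_e, p_ne)
    fitted = cloned.fit(L)
    assert sorted(fitted.ml_sequence_.tolist()) == list(range(4))
    stages = fitted.predict(L)
    assert stages.shape == (10,)
    assert np.all((stages >= 0) & (stages <= 4))


def test_result_serialization(tmp_path):
    rng = np.random.default_rng(12)
    p_e, p_ne = random_likelihood_instance(rng, 8, 4)
    L = EventLikelihoodMatrix(p_e, p_ne)
    result = fit_ebm(L, n_init=2, mcmc_iterations=500, burn_in=100, seed=0)
    result.to_json(tmp_path / "r.json")
    result.positional_variance_tsv(tmp_path / "pvd.tsv")
    import json

    with open(tmp_path / "r.json") as fh:
        payload = json.load(fh)
    assert sorted(payload["ml_sequence"]) == [0, 1, 2, 3]
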