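"""Observation binning, count-based estimation and Viterbi decoding.

Viterbi is checked against two independent oracles: exhaustive
enumeration of all state paths, and hmmlearn's CategoricalHMM decoder.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swallowsense.hmm import (SwallowHMM, bin_posterior, estimate_initial,
                              estimate_observations, estimate_transitions,
                              observation_bitmap, stationary_distribution,
                              viterbi)
from swallowsense.simulate import SimulationConfig, simulate_session

SUBJECT1_A = np.array([[0.76, 0.24], [0.96, 0.04]])
_SUBJECT1_B_PRINTED = np.array([
    [0.84, 0.03, 0.01, 0.00, 0.03, 0.01, 0.01, 0.01, 0.01, 0.06],
    [0.08, 0.02, 0.00, 0.00, 0.04, 0.00, 0.04, 0.02, 0.06, 0.74],
])
# the printed first row totals 1.01 (two-decimal rounding); renormalize
SUBJECT1_B = _SUBJECT1_B_PRINTED / _SUBJECT1_B_PRINTED.sum(axis=1, keepdims=True)


# -- posterior binning -------------------------------------------------------

def test_posterior_071_sets_eighth_bit():
    # 0.7 < 0.71 <= 0.8 -> window 8
    assert bin_posterior(0.71, 10) == 8
    np.testing.assert_array_equal(observation_bitmap(0.71, 10),
                                  [0, 0, 0, 0, 0, 0, 0, 1, 0, 0])


@pytest.mark.parametrize("p, expected", [(1.0, 10), (0.0, 1), (0.1, 1),
                                         (0.1000001, 2), (0.7, 7), (0.3, 3)])
def test_bin_boundaries(p, expected):
    assert bin_posterior(p, 10) == expected


def test_bin_rejects_out_of_range():
    with pytest.raises(ValueError):
        bin_posterior(1.2, 10)
    with pytest.raises(ValueError):
        bin_posterior(-0.1, 10)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(0.0, 1.0), st.integers(2, 20))
def test_bitmap_always_one_hot_in_correct_window(p, n):
    bits = observation_bitmap(p, n)
    assert bits.sum() == 1
    m = int(np.argmax(bits)) + 1
    if p == 0.0:
        assert m == 1
    else:
        assert (m - 1) / n < p + 1e-9 and p <= m / n + 1e-9


# -- estimation --------------------------------------------------------------

def test_transition_hand_count():
    # [n, n, s, n, n]: n->n twice, n->s once, s->n once
    A = estimate_transitions([[0, 0, 1, 0, 0]], smoothing=0.0)
    np.testing.assert_allclose(A, [[2 / 3, 1 / 3], [1.0, 0.0]])


def test_transition_unvisited_state_uniform_with_warning():
    with pytest.warns(UserWarning, match="never visited"):
        A = estimate_transitions([[0, 0, 0, 0]], smoothing=0.0)
    np.testing.assert_allclose(A[1], [0.5, 0.5])
    np.testing.assert_allclose(A.sum(axis=1), 1.0)


def test_transition_needs_length_two():
    with pytest.raises(ValueError):
        estimate_transitions([[0]])


def test_transition_no_cross_sequence_counting():
    # two sequences: a s->n transition must NOT be created at the
    # junction [.., 1] ++ [0, ..]
    with pytest.warns(UserWarning, match="never visited"):
        A = estimate_transitions([[0, 1], [0, 1]], smoothing=0.0)
    assert A[1, 0] == 0.5  # uniform fallback row (no s-> transitions)
    np.testing.assert_allclose(A[0], [0.0, 1.0])


def test_transition_recovery_from_simulated_sessions():
    labs, n = [], 0
    seed = 0
    while n < 5000:
        _, truth = simulate_session(SimulationConfig(duration=2000.0, seed=50 + seed))
        labs.append(truth.cycle_labels)
        n += truth.n_cycles
        seed += 1
    A = estimate_transitions(labs)
    assert np.abs(A - SUBJECT1_A).max() < 0.03


def test_observation_hand_count():
    B = estimate_observations([[0, 1]], [[0.05, 0.95]], smoothing=0.0)
    assert B[0, 0] == 1.0
    assert B[1, 9] == 1.0


def test_observation_rows_sum_to_one_any_input():
    rng = np.random.default_rng(0)
    labels = [rng.integers(0, 2, 30) for _ in range(3)]
    posts = [rng.random(30) for _ in range(3)]
    B = estimate_observations(labels, posts)
    np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)
    assert (B > 0).all()  # smoothing removes zeros


def test_observation_alignment_enforced():
    with pytest.raises(ValueError, match="align"):
        estimate_observations([[0, 1]], [[0.5]])


def test_initial_hand_count():
    pi = estimate_initial([[0], [0], [1]], smoothing=0.0)
    np.testing.assert_allclose(pi, [2 / 3, 1 / 3])


def test_initial_single_sequence_smoothed_off_degenerate():
    pi = estimate_initial([[0, 1, 0]])
    assert 0 < pi[1] < pi[0] < 1


def test_stationary_distribution_eigenvector_oracle():
    pi = stationary_distribution(SUBJECT1_A)
    # oracle: left eigenvector for eigenvalue 1
    w, v = np.linalg.eig(SUBJECT1_A.T)
    vec = np.real(v[:, np.argmin(np.abs(w - 1))])
    vec /= vec.sum()
    np.testing.assert_allclose(pi, vec, atol=1e-12)
    np.testing.assert_allclose(pi, [0.8, 0.2], atol=1e-12)
    hmm = SwallowHMM(initial="stationary").fit(
        [[0, 1, 0, 0]], [[0.1, 0.9, 0.2, 0.1]])
    np.testing.assert_allclose(hmm.startprob_,
                               stationary_distribution(hmm.transitions_))


# -- decoding ----------------------------------------------------------------

def _random_hmm(rng, n_bins=10):
    A = rng.dirichlet(np.ones(2), size=2)
    B = rng.dirichlet(np.ones(n_bins), size=2)
    pi = rng.dirichlet(np.ones(2))
    return pi, A, B


def _enumerate_best(pi, A, B, obs, floor=1e-12):
    lp = np.log(np.maximum(pi, floor))
    lA = np.log(np.maximum(A, floor))
    lB = np.log(np.maximum(B, floor))
    best = -np.inf
    for path in itertools.product([0, 1], repeat=len(obs)):
        ll = lp[path[0]] + lB[path[0], obs[0]]
        for a, b, o in zip(path[:-1], path[1:], obs[1:]):
            ll += lA[a, b] + lB[b, o]
        best = max(best, ll)
    return best


def test_empty_sequence_decodes_empty():
    hmm = SwallowHMM().set_matrices(SUBJECT1_A, np.full((2, 10), 0.1), [0.8, 0.2])
    assert hmm.predict([]).size == 0


def test_length_one_sequence_is_argmax_of_pi_times_b():
    pi, A, B = np.array([0.3, 0.7]), SUBJECT1_A, np.full((2, 10), 0.1)
    B = np.array([[0.5] + [0.5 / 9] * 9, [0.5 / 9] * 9 + [0.5]])
    path, _ = viterbi(pi, A, B, [0])
    assert path[0] == int(np.argmax(pi * B[:, 0]))


def test_viterbi_equals_exhaustive_enumeration():
    rng = np.random.default_rng(6)
    for _ in range(40):
        pi, A, B = _random_hmm(rng)
        L = int(rng.integers(1, 11))
        obs = rng.integers(0, 10, L)
        _, ll = viterbi(pi, A, B, obs)
        assert ll == pytest.approx(_enumerate_best(pi, A, B, obs), abs=1e-9)


def test_viterbi_matches_hmmlearn_oracle():
    from hmmlearn.hmm import CategoricalHMM
    rng = np.random.default_rng(7)
    for _ in range(10):
        pi, A, B = _random_hmm(rng)
        obs = rng.integers(0, 10, 50)
        _, ll = viterbi(pi, A, B, obs, floor=0.0)
        oracle = CategoricalHMM(n_components=2)
        oracle.startprob_, oracle.transmat_, oracle.emissionprob_ = pi, A, B
        ll_ref, _ = oracle.decode(obs.reshape(-1, 1), algorithm="viterbi")
        assert ll == pytest.approx(ll_ref, abs=1e-9)


def test_dominant_emissions_follow_bins():
    eps = 1e-6
    B = np.array([[1 - 9 * eps] + [eps] * 9, [eps] * 9 + [1 - 9 * eps]])
    A = np.full((2, 2), 0.5)
    hmm = SwallowHMM().set_matrices(A, B, [0.5, 0.5])
    post = [0.05, 0.95, 0.02, 0.99, 0.01]
    np.testing.assert_array_equal(hmm.predict(post), [0, 1, 0, 1, 0])


def test_exact_zero_entries_do_not_break_decoding():
    hmm = SwallowHMM().set_matrices(SUBJECT1_A, SUBJECT1_B, [0.8, 0.2])
    # observation in a zero-probability bin for both states (bin 4)
    path = hmm.predict([0.35, 0.35, 0.35])
    assert path.shape == (3,)


def test_posterior_decoder_agrees_on_easy_sequences():
    hmm_v = SwallowHMM(decoder="viterbi").set_matrices(SUBJECT1_A, SUBJECT1_B, [0.8, 0.2])
    hmm_p = SwallowHMM(decoder="posterior").set_matrices(SUBJECT1_A, SUBJECT1_B, [0.8, 0.2])
    post = [0.02, 0.05, 0.95, 0.03, 0.01, 0.98, 0.04]
    np.testing.assert_array_equal(hmm_v.predict(post), hmm_p.predict(post))


def test_locality_suppresses_long_swallow_runs():
    """With the printed transition structure (swallow->swallow = 0.04)
    decoding never emits 4+ consecutive swallow cycles."""
    hmm = SwallowHMM().set_matrices(SUBJECT1_A, SUBJECT1_B, [0.8, 0.2])
    rng = np.random.default_rng(8)
    for _ in range(50):
        post = rng.random(200)
        dec = hmm.predict(post)
        padded = np.concatenate([[0], dec, [0]])
        edges = np.flatnonzero(np.diff(padded)).reshape(-1, 2)
        run_lengths = edges[:, 1] - edges[:, 0] if len(edges) else np.array([0])
        assert run_lengths.max() < 4


def test_fit_rows_stochastic(fitted_svm):
    model, X, y, _, _ = fitted_svm
    post = model.posterior(X)
    hmm = SwallowHMM().fit([y], [post])
    np.testing.assert_allclose(hmm.transitions_.sum(axis=1), 1.0, atol=1e-9)
    np.testing.assert_allclose(hmm.emissions_.sum(axis=1), 1.0, atol=1e-9)
    assert hmm.startprob_.sum() == pytest.approx(1.0)
    assert (hmm.transitions_ >= 0).all() and (hmm.emissions_ >= 0).all()


def test_hmm_json_round_trip(tmp_path):
    hmm = SwallowHMM().set_matrices(SUBJECT1_A, SUBJECT1_B, [0.8, 0.2])
    hmm.to_json(tmp_path / "hmm.json")
    back = SwallowHMM.from_json(tmp_path / "hmm.json")
    post = [0.1, 0.9, 0.2, 0.75]
    np.testing.assert_array_equal(back.predict(post), hmm.predict(post))
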