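"""Two-state discrete-observation HMM refinement of SVM posteriors.

Breathing cycles form a hidden Markov chain over two states — normal
breathing (state 0) and cycle-with-swallow (state 1) — whose first-order
transition matrix A encodes swallow temporal locality: people rarely
swallow in consecutive breathing cycles, so the swallow→swallow entry is
small. The SVM posterior of each cycle is the observable: the [0, 1]
probability axis is divided into N equal windows (N = 10) and the window
the posterior falls in becomes a one-hot observation bitmap; e.g. with
N = 10 a posterior of 0.71 sets the eighth bit since 0.7 < 0.71 ≤ 0.8.

The model λ = (A, B, π) — transitions, 2×N observation matrix, initial
distribution — is estimated by direct counting from ground-truth labeled
training sequences (no Baum–Welch needed) with additive smoothing, and
test sequences are decoded to the maximum a posteriori state path by
Viterbi dynamic programming in log space (forward–backward posterior
decoding is available behind a flag).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

__all__ = [
    "bin_posterior",
    "observation_bitmap",
    "estimate_transitions",
    "estimate_observations",
    "estimate_initial",
    "stationary_distribution",
    "viterbi",
    "SwallowHMM",
]

DEFAULT_N_BINS = 10
PROB_FLOOR = 1e-12


def bin_posterior(p: float, n_bins: int = DEFAULT_N_BINS) -> int:
    """1-based index m of the posterior window: (m−1)/N < p ≤ m/N.

    p = 0 is assigned the first window by convention.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"posterior {p} outside [0, 1]")
    # round before ceil so p = 0.7 (binary 6.999...) lands in window 7
    m = int(np.ceil(round(p * n_bins, 9)))
    return max(m, 1)


def observation_bitmap(p: float, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """One-hot N-bit bitmap with the posterior's window bit set."""
    bits = np.zeros(n_bins, dtype=int)
    bits[bin_posterior(p, n_bins) - 1] = 1
    return bits


def _as_sequences(seqs) -> list[np.ndarray]:
    if len(seqs) and np.isscalar(seqs[0]):
        seqs = [seqs]
    return [np.asarray(s) for s in seqs]


def estimate_transitions(label_sequences, smoothing: float = 0.5) -> np.ndarray:
    """a_ij = count(i→j) / count(i→·), pooled over sequences.

    Transitions never cross sequence boundaries. Additive smoothing
    ``smoothing`` is applied to every count before row normalization; a
    state never left (no outgoing transitions) yields a uniform row with
    a warning.
    """
    seqs = _as_sequences(label_sequences)
    if not any(len(s) >= 2 for s in seqs):
        raise ValueError("need at least one sequence of length >= 2")
    counts = np.zeros((2, 2))
    for s in seqs:
        for i, j in zip(s[:-1], s[1:]):
            counts[int(i), int(j)] += 1
    A = counts + smoothing
    for i in range(2):
        if counts[i].sum() == 0:
            warnings.warn(f"state {i} never visited with a successor; "
                          "its transition row is set uniform", stacklevel=2)
            A[i] = 1.0
    return A / A.sum(axis=1, keepdims=True)


def estimate_observations(label_sequences, posterior_sequences,
                          n_bins: int = DEFAULT_N_BINS,
                          smoothing: float = 0.5) -> np.ndarray:
    """b_jm = count(state j emitted window m) / count(state j), smoothed."""
    labels = _as_sequences(label_sequences)
    posts = _as_sequences(posterior_sequences)
    if len(labels) != len(posts) or any(len(a) != len(b) for a, b in zip(labels, posts)):
        raise ValueError("label and posterior sequences must align")
    counts = np.zeros((2, n_bins))
    for lab, post in zip(labels, posts):
        for state, p in zip(lab, post):
            counts[int(state), bin_posterior(float(p), n_bins) - 1] += 1
    B = counts + smoothing
    return B / B.sum(axis=1, keepdims=True)


def estimate_initial(label_sequences, smoothing: float = 0.5) -> np.ndarray:
    """π_i = fraction of sequences starting in state i, smoothed."""
    seqs = _as_sequences(label_sequences)
    if not seqs:
        raise ValueError("need at least one sequence")
    counts = np.zeros(2)
    for s in seqs:
        counts[int(s[0])] += 1
    pi = counts + smoothing
    return pi / pi.sum()


def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Left unit eigenvector of a row-stochastic matrix (closed form for
    two states)."""
    A = np.asarray(A, dtype=float)
    denom = A[0, 1] + A[1, 0]
    if denom == 0:
        return np.array([0.5, 0.5])
    return np.array([A[1, 0], A[0, 1]]) / denom


def viterbi(start_prob: np.ndarray, transitions: np.ndarray,
            emissions: np.ndarray, observations: np.ndarray,
            floor: float = PROB_FLOOR) -> tuple[np.ndarray, float]:
    """MAP state path and its joint log probability.

    Probabilities are floored at ``floor`` before taking logs so exact
    zeros in the matrices never produce −inf recursions. Observations
    are 0-based window indices.
    """
    obs = np.asarray(observations, dtype=int)
    if obs.size == 0:
        return np.empty(0, dtype=int), 0.0
    log_pi = np.log(np.maximum(start_prob, floor))
    log_A = np.log(np.maximum(transitions, floor))
    log_B = np.log(np.maximum(emissions, floor))
    n_states = len(start_prob)
    T = obs.size
    delta = np.empty((T, n_states))
    psi = np.zeros((T, n_states), dtype=int)
    delta[0] = log_pi + log_B[:, obs[0]]
    for t in range(1, T):
        cand = delta[t - 1][:, None] + log_A  # cand[i, j]
        psi[t] = cand.argmax(axis=0)
        delta[t] = cand.max(axis=0) + log_B[:, obs[t]]
    path = np.empty(T, dtype=int)
    path[-1] = int(delta[-1].argmax())
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path, float(delta[-1].max())


def _posterior_decode(start_prob, transitions, emissions, observations,
                      floor: float = PROB_FLOOR) -> np.ndarray:
    """Per-cycle MAP (forward–backward) state decoding."""
    obs = np.asarray(observations, dtype=int)
    if obs.size == 0:
        return np.empty(0, dtype=int)
    log_pi = np.log(np.maximum(start_prob, floor))
    log_A = np.log(np.maximum(transitions, floor))
    log_B = np.log(np.maximum(emissions, floor))
    T = obs.size
    n = len(start_prob)
    alpha = np.empty((T, n))
    beta = np.zeros((T, n))
    alpha[0] = log_pi + log_B[:, obs[0]]
    for t in range(1, T):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + log_A, axis=0) + log_B[:, obs[t]]
    for t in range(T - 2, -1, -1):
        beta[t] = logsumexp(log_A + (log_B[:, obs[t + 1]] + beta[t + 1])[None, :], axis=1)
    return (alpha + beta).argmax(axis=1)


class SwallowHMM(BaseEstimator):
    """Supervised two-state HMM over posterior-probability observations.

    ``fit`` estimates λ = (A, B, π) by counting from ground-truth label
    sequences and aligned SVM posterior sequences; ``predict`` decodes a
    posterior sequence into refined {0 normal, 1 swallow} labels.

    Parameters
    ----------
    n_bins : number of equal posterior windows N (default 10).
    smoothing : additive smoothing applied to all count estimates; the
        per-subject matrices of real recordings contain exact zeros,
        which would otherwise make some observations impossible at
        decode time.
    decoder : "viterbi" (MAP path) or "posterior" (forward–backward,
        per-cycle MAP).
    initial : "counts" estimates π from sequence starts; "stationary"
        uses the stationary distribution of the fitted A.
    """

    def __init__(self, n_bins: int = DEFAULT_N_BINS, smoothing: float = 0.5,
                 floor: float = PROB_FLOOR, decoder: str = "viterbi",
                 initial: str = "counts"):
        self.n_bins = n_bins
        self.smoothing = smoothing
        self.floor = floor
        self.decoder = decoder
        self.initial = initial

    def fit(self, label_sequences, posterior_sequences) -> "SwallowHMM":
        self.transitions_ = estimate_transitions(label_sequences, self.smoothing)
        self.emissions_ = estimate_observations(label_sequences, posterior_sequences,
                                                self.n_bins, self.smoothing)
        if self.initial == "stationary":
            self.startprob_ = stationary_distribution(self.transitions_)
        else:
            self.startprob_ = estimate_initial(label_sequences, self.smoothing)
        return self

    @property
    def lambda_(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """The (A, B, π) tuple."""
        return self.transitions_, self.emissions_, self.startprob_

    def set_matrices(self, transitions, emissions, startprob) -> "SwallowHMM":
        """Install externally supplied λ = (A, B, π) (e.g. printed
        per-subject matrices)."""
        A = np.asarray(transitions, dtype=float)
        B = np.asarray(emissions, dtype=float)
        pi = np.asarray(startprob, dtype=float)
        if np.abs(A.sum(axis=1) - 1).max() > 1e-9 or np.abs(B.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("A and B rows must sum to 1")
        if abs(pi.sum() - 1) > 1e-9:
            raise ValueError("π must sum to 1")
        self.transitions_, self.emissions_, self.startprob_ = A, B, pi
        return self

    def observations(self, posteriors) -> np.ndarray:
        """0-based observation window indices for a posterior sequence."""
        return np.array([bin_posterior(float(p), self.n_bins) - 1
                         for p in np.asarray(posteriors, dtype=float)], dtype=int)

    def predict(self, posteriors) -> np.ndarray:
        """Refined {0, 1} labels for one posterior sequence."""
        obs = self.observations(posteriors)
        if self.decoder == "posterior":
            return _posterior_decode(self.startprob_, self.transitions_,
                                     self.emissions_, obs, self.floor)
        path, _ = viterbi(self.startprob_, self.transitions_, self.emissions_,
                          obs, self.floor)
        return path

    # -- persistence -------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> dict:
        blob = {"n_bins": self.n_bins,
                "transitions": self.transitions_.tolist(),
                "emissions": self.emissions_.tolist(),
                "startprob": self.startprob_.tolist()}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(blob, fh)
        return blob

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "SwallowHMM":
        if not isinstance(source, dict):
            with open(source) as fh:
                source = json.load(fh)
        model = cls(n_bins=int(source["n_bins"]))
        model.set_matrices(source["transitions"], source["emissions"], source["startprob"])
        return model
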