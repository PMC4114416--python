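"""HMM training and alignment, checked against independent oracles:
exhaustive path enumeration for Viterbi, closed-form M-steps for
single-state training, parameter recovery on sampled corpora, and
hmmlearn for the Gaussian-mixture emission pipeline."""

import itertools

import numpy as np
import pytest

from coughspot.errors import InputError
from coughspot.hmm import (
    Hmm,
    forward_log_likelihood,
    train_hmm,
    viterbi_align,
)
from coughspot.synthetic import sample_hmm_sequences

from conftest import fvs, make_hmm, random_hmm


def enumerate_viterbi(model, X):
    """Brute-force best path: score every legal left-to-right state
    sequence that starts in state 0 and ends in the last state."""
    n, T = model.n_states, X.shape[0]
    logB = model.emission_logprob(X)
    A, pi, ex = model.log_A, model.log_pi, model.log_exit
    best, best_path = -np.inf, None
    for path in itertools.product(range(n), repeat=T):
        score = pi[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            score += A[path[t - 1], path[t]] + logB[t, path[t]]
        score += ex[path[-1]]
        if score > best:
            best, best_path = score, path
    return best, best_path


class TestViterbiAlign:
    def test_one_state_path_and_score(self):
        m = make_hmm("x", [[[0.0, 0.0]]], [0.7])
        X = np.zeros((4, 2))
        path, score = viterbi_align(m, fvs(X))
        assert list(path) == [0, 0, 0, 0]
        expected = (m.emissions[0].log_pdf(X).sum()
                    + 3 * np.log(0.7) + np.log(0.3))
        assert score == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("n_states,T,seed", [
        (2, 3, 0), (2, 5, 1), (3, 4, 2), (3, 6, 3), (2, 6, 4), (3, 3, 5),
    ])
    def test_matches_exhaustive_enumeration(self, n_states, T, seed):
        rng = np.random.default_rng(seed)
        m = random_hmm(rng, "x", n_states)
        X = rng.normal(0, 3, size=(T, 2))
        path, score = viterbi_align(m, fvs(X))
        oracle_score, oracle_path = enumerate_viterbi(m, X)
        assert score == pytest.approx(oracle_score, abs=1e-9)
        assert tuple(path) == oracle_path

    def test_constant_loglik_shift_moves_score_not_path(self):
        """Adding the same constant to every frame log-likelihood (via an
        extra feature dimension with a fixed value under a unit
        Gaussian) shifts the score by T*c and leaves the path alone."""
        rng = np.random.default_rng(7)
        n_states, D, T = 2, 2, 6
        means = rng.normal(0, 3, size=(n_states, 1, D))
        self_probs = [0.7, 0.4]
        m1 = make_hmm("x", means, self_probs)
        # same model with one appended dimension: mean 0, variance 1
        means2 = np.concatenate([means, np.zeros((n_states, 1, 1))], axis=2)
        var2 = np.ones_like(means2)
        m2 = make_hmm("x", means2, self_probs, variances=var2)
        X = rng.normal(0, 2, size=(T, D))
        v = 1.7
        X2 = np.column_stack([X, np.full(T, v)])
        path1, s1 = viterbi_align(m1, fvs(X))
        path2, s2 = viterbi_align(m2, fvs(X2))
        c = -0.5 * np.log(2 * np.pi) - v ** 2 / 2.0
        assert np.array_equal(path1, path2)
        assert s2 == pytest.approx(s1 + T * c, abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        m = make_hmm("x", [[[0.0, 0.0]]], [0.5])
        with pytest.raises(InputError):
            viterbi_align(m, fvs(np.zeros((3, 5))))


class TestTrainHmm:
    def test_single_state_single_mixture_closed_form(self):
        """With one state and one mixture the M-step is the pooled
        frame mean and (floored, biased) pooled variance."""
        rng = np.random.default_rng(0)
        seqs = [fvs(rng.normal(1.5, 2.0, size=(20, 3))) for _ in range(5)]
        m = train_hmm("x", seqs, n_states=1, n_mix=1, max_iter=3, seed=0)
        pooled = np.concatenate([s.vectors for s in seqs])
        assert m.emissions[0].means[0] == pytest.approx(pooled.mean(axis=0), abs=1e-8)
        assert m.emissions[0].variances[0] == pytest.approx(
            np.maximum(pooled.var(axis=0), 1e-3), abs=1e-6)

    def test_em_loglik_monotone(self):
        rng = np.random.default_rng(1)
        truth = make_hmm("x", [[[0.0, 0.0]], [[4.0, -4.0]]], [0.8, 0.6])
        seqs = sample_hmm_sequences(truth, 30, 20, seed=2)
        m = train_hmm("x", seqs, n_states=2, n_mix=2, max_iter=15, seed=0)
        ll = np.array(m.train_log_likelihoods)
        assert len(ll) >= 2
        assert np.all(np.diff(ll) >= -1e-6)

    def test_transition_recovery_on_sampled_corpus(self):
        """Recovered self-transition probabilities within +/-0.05 of the
        generating chain, and error shrinks with corpus size."""
        truth = make_hmm("x", [[[0.0, 0.0]], [[6.0, -6.0]]], [0.9, 0.85])
        errs = []
        for n_seq in (40, 200):
            seqs = sample_hmm_sequences(truth, n_seq, 50, seed=3)
            m = train_hmm("x", seqs, n_states=2, n_mix=1, max_iter=20, seed=0)
            a_self = np.exp(np.diag(m.log_A))
            errs.append(np.abs(a_self - [0.9, 0.85]).max())
        assert errs[-1] <= 0.05
        assert errs[1] <= errs[0] + 0.01

    def test_deterministic_and_duplication_invariant(self):
        rng = np.random.default_rng(4)
        truth = make_hmm("x", [[[0.0, 0.0]], [[4.0, -4.0]]], [0.8, 0.6])
        seqs = sample_hmm_sequences(truth, 20, 15, seed=5)
        m1 = train_hmm("x", seqs, 2, 2, seed=9)
        m2 = train_hmm("x", seqs, 2, 2, seed=9)
        m3 = train_hmm("x", seqs + seqs, 2, 2, seed=9)
        assert np.array_equal(m1.log_transitions, m2.log_transitions)
        for e1, e3 in zip(m1.emissions, m3.emissions):
            assert e1.means == pytest.approx(e3.means, abs=1e-8)

    def test_variance_floor_enforced(self):
        seqs = [fvs(np.zeros((10, 2)))] * 3  # zero-variance corpus
        m = train_hmm("x", seqs, n_states=1, n_mix=1, max_iter=5, var_floor=1e-3)
        assert np.all(m.emissions[0].variances >= 1e-3)

    def test_short_sequence_rejected(self):
        with pytest.raises(InputError):
            train_hmm("x", [fvs(np.zeros((2, 2)))], n_states=3)


class TestHmmlearnCrossCheck:
    def test_emission_pipeline_matches_hmmlearn(self):
        """On a single-emitting-state mixture model our score equals
        hmmlearn's plus the closed-form entry/exit adjustment
        (hmmlearn has no exit pseudo-state)."""
        hmmlearn_hmm = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(11)
        means = rng.normal(0, 2, size=(1, 2, 3))  # 1 state, 2 mixtures, D=3
        varis = rng.uniform(0.5, 2.0, size=(1, 2, 3))
        w = np.array([[0.3, 0.7]])
        m = make_hmm("x", means, [0.6], variances=varis, weights=w)
        X = rng.normal(0, 2, size=(12, 3))
        ref = hmmlearn_hmm.GMMHMM(
            n_components=1, n_mix=2, covariance_type="diag",
            init_params="", params="")
        ref.startprob_ = np.array([1.0])
        ref.transmat_ = np.array([[1.0]])
        ref.weights_ = w
        ref.means_ = means
        ref.covars_ = varis
        adjustment = 11 * np.log(0.6) + np.log(0.4)  # (T-1) self + exit
        ours = forward_log_likelihood(m, fvs(X))
        assert ours == pytest.approx(ref.score(X) + adjustment, abs=1e-8)


class TestSerialization:
    def test_json_round_trip_lossless(self, tmp_path):
        rng = np.random.default_rng(6)
        m = random_hmm(rng, "cough", 3)
        p = tmp_path / "m.json"
        m.save_json(p)
        m2 = Hmm.load_json(p)
        assert m2.label == m.label
        assert np.allclose(
            np.where(np.isinf(m.log_transitions), -1e30, m.log_transitions),
            np.where(np.isinf(m2.log_transitions), -1e30, m2.log_transitions),
            atol=1e-12)
        for e1, e2 in zip(m.emissions, m2.emissions):
            assert np.allclose(e1.means, e2.means, atol=1e-12)
            assert np.allclose(e1.variances, e2.variances, atol=1e-12)
            assert np.allclose(e1.weights, e2.weights, atol=1e-12)
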