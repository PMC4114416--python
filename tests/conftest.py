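import numpy as np
import pytest

from coughspot import benchmark as bm
from coughspot.features import FeatureVectorSequence
from coughspot.hmm import GaussianMixtureEmission, Hmm, left_to_right_transitions


def make_hmm(label, means, self_probs, variances=None, weights=None, seed=None):
    """Build a 1-mixture-per-state (or given-mixture) left-to-right HMM
    directly from parameters, for oracle and sampling tests."""
    means = np.atleast_3d(np.asarray(means, dtype=float))  # (n_states, M, D)
    n_states = means.shape[0]
    if variances is None:
        variances = np.ones_like(means)
    emissions = [
        GaussianMixtureEmission(
            np.ones(means.shape[1]) / means.shape[1] if weights is None else weights[j],
            means[j], variances[j],
        )
        for j in range(n_states)
    ]
    A = np.full((n_states + 2, n_states + 2), -np.inf)
    A[0, 1] = 0.0
    for j, p in enumerate(self_probs):
        A[j + 1, j + 1] = np.log(p)
        A[j + 1, j + 2] = np.log(1.0 - p)
    return Hmm(label, n_states, A, emissions)


def random_hmm(rng, label, n_states, D=2):
    means = rng.normal(0, 3, size=(n_states, 1, D))
    self_probs = rng.uniform(0.2, 0.8, size=n_states)
    return make_hmm(label, means, self_probs)


def fvs(X):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return FeatureVectorSequence(X, np.arange(X.shape[0]) * 0.01, "test")


@pytest.fixture(scope="session")
def small_network():
    """A small but functional trained network shared by detection tests.

    Trained on a reduced synthetic corpus (40 cough + 40 background
    clips) — enough for reliable detection at high SNR.
    """
    return bm.train_default_network(seed=1, n_cough=40, n_background=40)
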