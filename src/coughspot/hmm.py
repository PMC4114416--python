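"""Hidden Markov models with Gaussian-mixture emissions.

Each sound class (cough, background, door slam, ...) is modelled by a
left-to-right HMM with self-loops, diagonal-covariance Gaussian mixture
emissions, and non-emitting entry/exit pseudo-states — the word-model
convention of classical keyword spotting.  Training is Baum-Welch (EM)
over a corpus of labelled feature sequences; all probability arithmetic
is in the log domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

from .errors import InputError, NumericError
from .features import FeatureVectorSequence

LOG_ZERO = -np.inf
_LOG_2PI = np.log(2.0 * np.pi)

SERIALIZATION_FORMAT = "coughspot-hmm"
SERIALIZATION_VERSION = 1


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    """Stable log-sum-exp that tolerates all-(-inf) slices."""
    m = np.max(a, axis=axis, keepdims=True)
    m_safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        out = np.log(np.sum(np.exp(a - m_safe), axis=axis))
    return out + np.squeeze(m_safe, axis=axis) + np.where(
        np.isfinite(np.squeeze(m, axis=axis)), 0.0, LOG_ZERO
    )


@dataclass
class GaussianMixtureEmission:
    """Diagonal-covariance Gaussian mixture observation density."""

    weights: np.ndarray   # (M,), simplex
    means: np.ndarray     # (M, D)
    variances: np.ndarray  # (M, D), all >= variance floor

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.asarray(self.means, dtype=np.float64)
        self.variances = np.asarray(self.variances, dtype=np.float64)
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise InputError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise InputError("mixture variances must be positive")

    @property
    def n_mix(self) -> int:
        return len(self.weights)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def log_pdf_components(self, X: np.ndarray) -> np.ndarray:
        """Per-component weighted log density, shape (T, M)."""
        D = self.n_features
        inv = 1.0 / self.variances                        # (M, D)
        const = -0.5 * (D * _LOG_2PI + np.log(self.variances).sum(axis=1))
        quad = (
            0.5 * (X ** 2) @ inv.T
            - X @ (self.means * inv).T
            + 0.5 * ((self.means ** 2) * inv).sum(axis=1)
        )
        with np.errstate(divide="ignore"):
            logw = np.log(self.weights)
        return logw + const - quad

    def log_pdf(self, X: np.ndarray) -> np.ndarray:
        return _logsumexp(self.log_pdf_components(X), axis=1)


@dataclass
class Hmm:
    """A left-to-right HMM for one sound class.

    ``log_transitions`` is an (n_states + 2) square matrix over
    [entry, emitting states..., exit]; the entry and exit states do not
    emit.  Rows of ``exp(log_transitions)`` sum to one over reachable
    successors (the exit row is absorbing and all-zero).
    """

    label: str
    n_states: int
    log_transitions: np.ndarray
    emissions: List[GaussianMixtureEmission]
    train_log_likelihoods: List[float] = field(default_factory=list, repr=False)

    @property
    def n_features(self) -> int:
        return self.emissions[0].n_features

    @property
    def log_pi(self) -> np.ndarray:
        """Entry-state transition row over the emitting states."""
        return self.log_transitions[0, 1:-1]

    @property
    def log_A(self) -> np.ndarray:
        """Emitting-to-emitting transition block, (n, n)."""
        return self.log_transitions[1:-1, 1:-1]

    @property
    def log_exit(self) -> np.ndarray:
        """Emitting-to-exit transition column, (n,)."""
        return self.log_transitions[1:-1, -1]

    def emission_logprob(self, X: np.ndarray) -> np.ndarray:
        """State-wise observation log likelihoods, shape (T, n_states)."""
        return np.column_stack([e.log_pdf(X) for e in self.emissions])

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": SERIALIZATION_FORMAT,
            "version": SERIALIZATION_VERSION,
            "label": self.label,
            "n_states": self.n_states,
            "log_transitions": self.log_transitions.tolist(),
            "emissions": [
                {
                    "weights": e.weights.tolist(),
                    "means": e.means.tolist(),
                    "variances": e.variances.tolist(),
                }
                for e in self.emissions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Hmm":
        if d.get("format") != SERIALIZATION_FORMAT:
            raise InputError("not a serialized HMM")
        trans = np.array(d["log_transitions"], dtype=np.float64)
        # JSON has no -inf; nulls round-trip to NaN and are restored here
        trans = np.where(np.isnan(trans), LOG_ZERO, trans)
        return cls(
            label=d["label"],
            n_states=int(d["n_states"]),
            log_transitions=trans,
            emissions=[
                GaussianMixtureEmission(
                    np.array(e["weights"]), np.array(e["means"]), np.array(e["variances"])
                )
                for e in d["emissions"]
            ],
        )

    def save_json(self, path) -> None:
        d = self.to_dict()
        # replace -inf with null for strict JSON
        d["log_transitions"] = [
            [None if x == LOG_ZERO else x for x in row] for row in d["log_transitions"]
        ]
        with open(path, "w") as fh:
            json.dump(d, fh, sort_keys=True)

    @classmethod
    def load_json(cls, path) -> "Hmm":
        with open(path) as fh:
            d = json.load(fh)
        d["log_transitions"] = [
            [np.nan if x is None else x for x in row] for row in d["log_transitions"]
        ]
        return cls.from_dict(d)


def left_to_right_transitions(n_states: int, self_prob: float = 0.6,
                              final_self_prob: float | None = None) -> np.ndarray:
    """Log transition matrix for a left-to-right chain with self-loops."""
    if final_self_prob is None:
        final_self_prob = self_prob
    A = np.full((n_states + 2, n_states + 2), LOG_ZERO)
    A[0, 1] = 0.0  # entry always starts in the first emitting state
    for j in range(1, n_states):
        A[j, j] = np.log(self_prob)
        A[j, j + 1] = np.log(1.0 - self_prob)
    A[n_states, n_states] = np.log(final_self_prob)
    A[n_states, n_states + 1] = np.log(1.0 - final_self_prob)
    return A


def _check_dims(model: Hmm, feats: FeatureVectorSequence) -> np.ndarray:
    X = np.asarray(feats.vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise InputError(
            f"feature dimension {X.shape[1] if X.ndim == 2 else '?'} does not "
            f"match model dimension {model.n_features}"
        )
    return X


def forward_log_likelihood(model: Hmm, feats: FeatureVectorSequence) -> float:
    """Total log P(observations | model), summed over all state paths."""
    X = _check_dims(model, feats)
    logB = model.emission_logprob(X)
    return _forward(model, logB)[1]


def _forward(model: Hmm, logB: np.ndarray) -> Tuple[np.ndarray, float]:
    # left-to-right topology: only self (diagonal) and advance
    # (superdiagonal) transitions, so the recursion is tridiagonal
    T, n = logB.shape
    A = model.log_A
    d0 = np.diag(A).copy()
    d1 = np.diag(A, 1).copy() if n > 1 else np.empty(0)
    alpha = np.empty((T, n))
    alpha[0] = model.log_pi + logB[0]
    adv = np.empty(n)
    adv[0] = LOG_ZERO
    for t in range(1, T):
        prev = alpha[t - 1]
        adv[1:] = prev[:-1] + d1
        alpha[t] = np.logaddexp(prev + d0, adv) + logB[t]
    ll = _logsumexp(alpha[T - 1] + model.log_exit, axis=0)
    return alpha, float(ll)


def _backward(model: Hmm, logB: np.ndarray) -> np.ndarray:
    T, n = logB.shape
    A = model.log_A
    d0 = np.diag(A).copy()
    d1 = np.diag(A, 1).copy() if n > 1 else np.empty(0)
    beta = np.empty((T, n))
    beta[T - 1] = model.log_exit
    adv = np.empty(n)
    adv[-1] = LOG_ZERO
    for t in range(T - 2, -1, -1):
        nxt = logB[t + 1] + beta[t + 1]
        adv[:-1] = d1 + nxt[1:]
        beta[t] = np.logaddexp(d0 + nxt, adv)
    return beta


def viterbi_align(model: Hmm, feats: FeatureVectorSequence) -> Tuple[np.ndarray, float]:
    """Best state path through a single model and its joint log score.

    The path is constrained to end in a state with an exit transition.
    Exact score ties are broken toward the lowest predecessor state
    index, making alignment deterministic.
    """
    X = _check_dims(model, feats)
    if X.shape[0] == 0:
        raise InputError("cannot align an empty feature sequence")
    logB = model.emission_logprob(X)
    T, n = logB.shape
    A = model.log_A
    delta = model.log_pi + logB[0]
    bp = np.zeros((T, n), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + A  # (from, to)
        bp[t] = np.argmax(cand, axis=0)  # argmax returns the lowest index on ties
        delta = cand[bp[t], np.arange(n)] + logB[t]
    final = delta + model.log_exit
    last = int(np.argmax(final))
    score = float(final[last])
    if not np.isfinite(score):
        raise NumericError("no admissible state path (sequence too short for topology?)")
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = last
    for t in range(T - 1, 0, -1):
        path[t - 1] = bp[t, path[t]]
    return path, score


def _init_model(label: str, sequences: List[np.ndarray], n_states: int,
                n_mix: int, seed: int, var_floor: float) -> Hmm:
    """Uniform-segmentation initialization with k-means mixture splitting."""
    pools: List[List[np.ndarray]] = [[] for _ in range(n_states)]
    for X in sequences:
        T = X.shape[0]
        bounds = (np.arange(n_states + 1) * T) // n_states
        for j in range(n_states):
            pools[j].append(X[bounds[j]:bounds[j + 1]])
    emissions = []
    for j in range(n_states):
        P = np.concatenate(pools[j], axis=0)
        pooled_var = np.maximum(P.var(axis=0), var_floor)
        if n_mix == 1 or P.shape[0] < 2 * n_mix:
            em = GaussianMixtureEmission(
                np.ones(max(n_mix, 1)) / max(n_mix, 1),
                np.tile(P.mean(axis=0), (max(n_mix, 1), 1)),
                np.tile(pooled_var, (max(n_mix, 1), 1)),
            )
        else:
            km = KMeans(n_clusters=n_mix, n_init=1, random_state=seed).fit(P)
            w = np.zeros(n_mix)
            means = np.zeros((n_mix, P.shape[1]))
            varis = np.zeros((n_mix, P.shape[1]))
            for m in range(n_mix):
                members = P[km.labels_ == m]
                if members.shape[0] < 2:
                    members = P
                w[m] = max(members.shape[0], 1)
                means[m] = members.mean(axis=0)
                varis[m] = np.maximum(members.var(axis=0), var_floor)
            w = w / w.sum()
            em = GaussianMixtureEmission(w, means, varis)
        emissions.append(em)
    return Hmm(label, n_states, left_to_right_transitions(n_states), emissions)


def train_hmm(label: str, sequences: Sequence[FeatureVectorSequence],
              n_states: int, n_mix: int = 2, tol: float = 1e-3,
              max_iter: int = 25, seed: int = 0,
              var_floor: float = 1e-3) -> Hmm:
    """Fit a left-to-right HMM to labelled feature sequences by Baum-Welch.

    The per-iteration total log-likelihood is non-decreasing (EM
    guarantee) and is recorded on the returned model as
    ``train_log_likelihoods``.  Training is deterministic for a fixed
    seed; the seed controls only the k-means mixture initialization.

    Raises
    ------
    InputError
        If any sequence is shorter than ``n_states`` frames (a
        left-to-right path cannot traverse the chain).
    NumericError
        If the likelihood becomes non-finite, naming the iteration.
    """
    if len(sequences) == 0:
        raise InputError("need at least one training sequence")
    if n_mix < 1:
        raise InputError("n_mix must be >= 1")
    Xs = [np.asarray(s.vectors, dtype=np.float64) for s in sequences]
    for i, X in enumerate(Xs):
        if X.shape[0] < n_states:
            raise InputError(
                f"sequence {i} has {X.shape[0]} frames < n_states={n_states}"
            )
    model = _init_model(label, Xs, n_states, n_mix, seed, var_floor)
    n, D = n_states, Xs[0].shape[1]
    history: List[float] = []
    prev_ll = -np.inf
    for it in range(max_iter):
        occ = np.zeros((n, n_mix))
        mean_acc = np.zeros((n, n_mix, D))
        sq_acc = np.zeros((n, n_mix, D))
        self_acc = np.zeros(n)
        adv_acc = np.zeros(n)
        exit_acc = np.zeros(n)
        total_ll = 0.0
        logA = model.log_A
        for X in Xs:
            T = X.shape[0]
            comp = np.stack([e.log_pdf_components(X) for e in model.emissions], axis=1)
            logB = _logsumexp(comp, axis=2)  # (T, n)
            alpha, ll = _forward(model, logB)
            if not np.isfinite(ll):
                raise NumericError(f"non-finite likelihood at EM iteration {it}")
            beta = _backward(model, logB)
            total_ll += ll
            gamma = np.exp(alpha + beta - ll)  # (T, n)
            # mixture-component responsibilities
            resp = gamma[:, :, None] * np.exp(comp - logB[:, :, None])
            occ += resp.sum(axis=0)
            mean_acc += np.einsum("tjm,td->jmd", resp, X)
            sq_acc += np.einsum("tjm,td->jmd", resp, X ** 2)
            # transition statistics (self / advance / exit)
            if T > 1:
                sl = np.exp(
                    alpha[:-1] + np.diag(logA)[None, :] + logB[1:] + beta[1:] - ll
                ).sum(axis=0)
                self_acc += sl
                adv = np.exp(
                    alpha[:-1, :-1] + np.diag(logA, 1)[None, :]
                    + logB[1:, 1:] + beta[1:, 1:] - ll
                ).sum(axis=0)
                adv_acc[:-1] += adv
            exit_acc += np.exp(alpha[T - 1] + model.log_exit - ll)
        history.append(total_ll)
        # ---- M-step ----
        new_trans = np.full_like(model.log_transitions, LOG_ZERO)
        new_trans[0, 1] = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            for j in range(n):
                denom = self_acc[j] + adv_acc[j] + exit_acc[j]
                if denom <= 0:
                    new_trans[j + 1] = model.log_transitions[j + 1]
                    continue
                if self_acc[j] > 0:
                    new_trans[j + 1, j + 1] = np.log(self_acc[j] / denom)
                if j < n - 1 and adv_acc[j] > 0:
                    new_trans[j + 1, j + 2] = np.log(adv_acc[j] / denom)
                if exit_acc[j] > 0:
                    new_trans[j + 1, n + 1] = np.log(exit_acc[j] / denom)
        new_emissions = []
        for j in range(n):
            w = occ[j].copy()
            means = model.emissions[j].means.copy()
            varis = model.emissions[j].variances.copy()
            for m in range(n_mix):
                if occ[j, m] > 1e-10:
                    means[m] = mean_acc[j, m] / occ[j, m]
                    varis[m] = np.maximum(
                        sq_acc[j, m] / occ[j, m] - means[m] ** 2, var_floor
                    )
            if w.sum() > 0:
                w = w / w.sum()
            else:
                w = model.emissions[j].weights
            new_emissions.append(GaussianMixtureEmission(w, means, varis))
        model = Hmm(label, n, new_trans, new_emissions, history)
        if np.isfinite(prev_ll) and total_ll - prev_ll < tol:
            break
        prev_ll = total_ll
    model.train_log_likelihoods = history
    return model
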