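"""Keyword-spotting recognition network and token-passing decoder.

The network joins one cough model with one or more filler models in a
closed loop grammar: any model may follow any model, with an optional
log-domain insertion penalty charged at each inter-model transition.
Decoding propagates scored tokens through every model's states and,
at each frame, lets the best exiting token re-enter the loop — an exact
Viterbi search over the composed network when no beam is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .errors import ConfigurationError, InputError
from .features import FeatureVectorSequence
from .hmm import LOG_ZERO, Hmm

# tie preference: stay in the model (self), then advance, then re-enter
# the loop — exact ties must not fragment a span into insertions
_BP_SELF, _BP_ADV, _BP_ENTRY = 0, 1, 2


@dataclass
class LabelSpan:
    """One decoded span: a model label covering [start_frame, end_frame)."""

    label: str
    start_frame: int
    end_frame: int
    log_score: float


@dataclass
class DecodedPath:
    """Best label segmentation of a frame sequence under the loop grammar."""

    labels: List[LabelSpan]
    total_log_score: float

    def spans_for(self, label: str) -> List[LabelSpan]:
        return [s for s in self.labels if s.label == label]


@dataclass
class RecognitionNetwork:
    """A closed loop of class HMMs for keyword spotting.

    Exactly one model carries ``target_label`` (the keyword, by default
    "cough"); the remaining models are fillers absorbing everything
    else.  ``loop_penalty`` (log domain, <= 0 discourages insertions) is
    added every time a token crosses from one model into the next.
    """

    models: List[Hmm]
    loop_penalty: float = 0.0
    target_label: str = "cough"

    def __post_init__(self) -> None:
        labels = [m.label for m in self.models]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate model labels in network")

    @property
    def n_features(self) -> int:
        return self.models[0].n_features

    def model(self, label: str) -> Hmm:
        for m in self.models:
            if m.label == label:
                return m
        raise KeyError(label)

    def save_json(self, path) -> None:
        d = {
            "format": "coughspot-network",
            "version": 1,
            "loop_penalty": self.loop_penalty,
            "target_label": self.target_label,
            "models": [m.to_dict() for m in self.models],
        }
        for md in d["models"]:
            md["log_transitions"] = [
                [None if x == LOG_ZERO else x for x in row]
                for row in md["log_transitions"]
            ]
        with open(path, "w") as fh:
            json.dump(d, fh, sort_keys=True)

    @classmethod
    def load_json(cls, path) -> "RecognitionNetwork":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("format") != "coughspot-network":
            raise InputError("not a serialized recognition network")
        models = []
        for md in d["models"]:
            md["log_transitions"] = [
                [np.nan if x is None else x for x in row]
                for row in md["log_transitions"]
            ]
            models.append(Hmm.from_dict(md))
        return cls(models, float(d["loop_penalty"]), d["target_label"])


class _FlatNetwork:
    """Flattened state-space view of a network, reused across segments."""

    def __init__(self, net: RecognitionNetwork):
        if not net.models:
            raise ConfigurationError("recognition network has no models")
        dims = {m.n_features for m in net.models}
        if len(dims) != 1:
            raise ConfigurationError("models disagree on feature dimension")
        self.net = net
        self.model_of: List[int] = []
        self.is_first = []
        log_self, log_adv, log_exit, log_entry = [], [], [], []
        for mi, m in enumerate(net.models):
            A, pi, ex = m.log_A, m.log_pi, m.log_exit
            for j in range(m.n_states):
                self.model_of.append(mi)
                self.is_first.append(j == 0)
                log_entry.append(pi[j])
                log_self.append(A[j, j])
                log_adv.append(A[j - 1, j] if j > 0 else LOG_ZERO)
                log_exit.append(ex[j])
        self.S = len(self.model_of)
        self.model_of = np.array(self.model_of)
        self.is_first = np.array(self.is_first)
        self.log_entry = np.array(log_entry)
        self.log_self = np.array(log_self)
        self.log_adv = np.array(log_adv)  # from global state s-1 (same model)
        self.log_exit = np.array(log_exit)

    def emissions(self, X: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [m.emission_logprob(X) for m in self.net.models], axis=1
        )


def decode_token_passing(net: RecognitionNetwork, feats: FeatureVectorSequence,
                         beam: Optional[float] = None) -> DecodedPath:
    """Decode a feature sequence against the loop grammar.

    With ``beam=None`` (the default) the search is exact: the result is
    the max-probability (model sequence, state path) pair over the
    composed network, with ``loop_penalty`` added per inter-model
    transition.  An empty input decodes to an empty path.

    ``beam``, when given, prunes tokens more than ``beam`` below the
    per-frame best (an approximation; off by default since desk-scale
    inputs do not need it).
    """
    flat = _FlatNetwork(net)
    X = np.asarray(feats.vectors, dtype=np.float64)
    if X.ndim != 2 or (X.size and X.shape[1] != net.n_features):
        raise InputError("feature dimension does not match network models")
    T = X.shape[0]
    if T == 0:
        return DecodedPath([], 0.0)
    E = flat.emissions(X)  # (T, S)
    S = flat.S
    entry0 = np.where(flat.is_first, flat.log_entry, LOG_ZERO)
    delta = entry0 + E[0]
    bp = np.zeros((T, S), dtype=np.int8)
    loop_src = np.zeros(T, dtype=np.int64)
    D = np.empty((T, S))
    D[0] = delta
    for t in range(1, T):
        exits = delta + flat.log_exit
        src = int(np.argmax(exits))
        loop_best = exits[src] + net.loop_penalty
        loop_src[t] = src
        cand_entry = np.where(flat.is_first, loop_best + flat.log_entry, LOG_ZERO)
        cand_self = delta + flat.log_self
        cand_adv = np.empty(S)
        cand_adv[0] = LOG_ZERO
        cand_adv[1:] = delta[:-1] + flat.log_adv[1:]
        stacked = np.stack([cand_self, cand_adv, cand_entry])
        bp[t] = np.argmax(stacked, axis=0)
        delta = stacked[bp[t], np.arange(S)] + E[t]
        if beam is not None:
            delta = np.where(delta < delta.max() - beam, LOG_ZERO, delta)
        D[t] = delta
    final = delta + flat.log_exit
    s = int(np.argmax(final))
    total = float(final[s])
    if not np.isfinite(total):
        raise ConfigurationError(
            "no admissible decoding (input shorter than every model topology?)"
        )
    # ---- traceback of label spans ----
    spans: List[LabelSpan] = []
    end = T
    end_score = total
    t = T - 1
    while t >= 0:
        if t == 0 or bp[t, s] == _BP_ENTRY:
            start = t
            start_score = 0.0 if t == 0 else float(D[t - 1, loop_src[t]] + flat.log_exit[loop_src[t]])
            spans.append(LabelSpan(
                label=net.models[flat.model_of[s]].label,
                start_frame=start,
                end_frame=end,
                log_score=end_score - start_score,
            ))
            end = t
            end_score = start_score
            if t == 0:
                break
            s = loop_src[t]
            t -= 1
        elif bp[t, s] == _BP_ADV:
            s -= 1
            t -= 1
        else:
            t -= 1
    spans.reverse()
    return DecodedPath(spans, total)
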