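"""Seeded generators for every input the monitoring pipeline consumes.

Acoustic scenes emulate ambulatory recordings: parametric cough bursts
(band-filtered noise with a sharp attack, exponential decay and an
optional short voiced tail) embedded at a controlled signal-to-noise
ratio in a background bed of speech-like babble, steady mains hum, and
impulsive door slams — the confuser classes an in-the-wild cough
detector must reject.  Activity traces, HMM-sampled feature corpora
and Likert survey tables support the activity, training and survey
statistics respectively.  Every generator is a pure function of its
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import signal
from scipy.stats import norm

from .audio import AudioRecording
from .activity import SCALE_MAX, AccelerometerTrace
from .errors import InputError
from .features import FeatureVectorSequence
from .hmm import Hmm
from .metrics import EventLabelSet, SurveyResponse, N_SURVEY_ITEMS

DEFAULT_SR = 16000


@dataclass
class CoughParams:
    """Acoustic parameters of one synthetic cough burst."""

    burst_duration_s: float = 0.15
    attack_s: float = 0.008
    decay_rate: float = 18.0        # 1/s exponential envelope decay
    band_low_hz: float = 300.0
    band_high_hz: float = 3000.0
    voiced_tail: bool = False
    amplitude: float = 0.7

    def validate(self, sample_rate_hz: int) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz < sample_rate_hz / 2):
            raise InputError("require 0 < band_low < band_high < Nyquist")
        if self.burst_duration_s <= 0 or self.attack_s <= 0:
            raise InputError("durations must be positive")
        if not 0 <= self.amplitude <= 1:
            raise InputError("amplitude must be in [0, 1]")


@dataclass
class SceneSpec:
    """A labelled acoustic scene: coughs over a distractor background."""

    duration_s: float = 60.0
    n_coughs: int = 5
    snr_db: float = 10.0
    distractors: Tuple[str, ...] = ("babble", "hum")
    seed: int = 0
    segment_s: float = 6.0
    allow_boundary_straddle: bool = False
    slam_rate_per_min: float = 1.0


def _bandpass(x: np.ndarray, lo: float, hi: float, sr: int) -> np.ndarray:
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sr, output="sos")
    return signal.sosfilt(sos, x)


def synth_cough(params: CoughParams, sample_rate_hz: int = DEFAULT_SR,
                seed: int = 0) -> AudioRecording:
    """Synthesize one cough burst; deterministic per (params, seed)."""
    params.validate(sample_rate_hz)
    rng = np.random.default_rng(seed)
    n = int(round(params.burst_duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    noise = rng.standard_normal(n)
    burst = _bandpass(noise, params.band_low_hz, params.band_high_hz, sample_rate_hz)
    attack = np.minimum(t / params.attack_s, 1.0)
    envelope = attack * np.exp(-params.decay_rate * np.maximum(t - params.attack_s, 0.0))
    x = burst * envelope
    if params.voiced_tail:
        n_tail = int(round(0.08 * sample_rate_hz))
        tt = np.arange(n_tail) / sample_rate_hz
        f0 = rng.uniform(180.0, 260.0)
        tail = 0.25 * (np.sin(2 * np.pi * f0 * tt)
                       + 0.4 * np.sin(2 * np.pi * 2 * f0 * tt)) * np.exp(-25.0 * tt)
        x = np.concatenate([x, tail])
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x * (params.amplitude / peak)
    return AudioRecording(x, sample_rate_hz)


def synth_babble(duration_s: float, sample_rate_hz: int = DEFAULT_SR,
                 seed: int = 0) -> AudioRecording:
    """Speech-like babble: formant-band noise with syllabic modulation."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    x = np.zeros(n)
    for lo, hi in [(300, 800), (800, 1800), (1800, 3200)]:
        band = _bandpass(rng.standard_normal(n), lo, hi, sample_rate_hz)
        rate = rng.uniform(2.5, 5.0)       # syllables/second
        phase = rng.uniform(0, 2 * np.pi)
        am = 0.5 * (1.0 + np.sin(2 * np.pi * rate * t + phase))
        x += band * am * rng.uniform(0.4, 1.0)
    peak = np.max(np.abs(x))
    return AudioRecording(x / peak * 0.5 if peak > 0 else x, sample_rate_hz)


def synth_hum(duration_s: float, sample_rate_hz: int = DEFAULT_SR,
              seed: int = 0, base_hz: float = 60.0) -> AudioRecording:
    """Steady mains-style hum: fundamental plus weak harmonics."""
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    x = np.zeros(n)
    for k, amp in [(1, 1.0), (2, 0.5), (3, 0.25)]:
        x += amp * np.sin(2 * np.pi * base_hz * k * t + rng.uniform(0, 2 * np.pi))
    peak = np.max(np.abs(x))
    return AudioRecording(x / peak * 0.3 if peak > 0 else x, sample_rate_hz)


def synth_door_slam(sample_rate_hz: int = DEFAULT_SR, seed: int = 0) -> AudioRecording:
    """Impulsive door slam: low-frequency thump with a fast broadband edge."""
    rng = np.random.default_rng(seed)
    dur = 0.35
    n = int(round(dur * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    thump_f = rng.uniform(55.0, 110.0)
    thump = np.sin(2 * np.pi * thump_f * t) * np.exp(-12.0 * t)
    edge = _bandpass(rng.standard_normal(n), 80.0, 1200.0, sample_rate_hz)
    edge *= np.minimum(t / 0.002, 1.0) * np.exp(-30.0 * t)
    x = thump + 0.7 * edge
    peak = np.max(np.abs(x))
    return AudioRecording(x / peak * 0.8 if peak > 0 else x, sample_rate_hz)


def _sample_cough_params(rng: np.random.Generator) -> CoughParams:
    return CoughParams(
        burst_duration_s=float(rng.uniform(0.08, 0.30)),
        attack_s=float(rng.uniform(0.004, 0.012)),
        decay_rate=float(rng.uniform(12.0, 25.0)),
        band_low_hz=float(rng.uniform(250.0, 400.0)),
        band_high_hz=float(rng.uniform(2500.0, 3500.0)),
        voiced_tail=bool(rng.random() < 0.3),
        amplitude=0.7,
    )


def _place_events(rng: np.random.Generator, spec: SceneSpec,
                  durations: Sequence[float]) -> List[float]:
    """Non-overlapping start times; by default each event stays inside
    one processing segment."""
    starts: List[float] = []
    seg = spec.segment_s
    n_segments = int(spec.duration_s // seg)
    if not spec.allow_boundary_straddle:
        if spec.n_coughs > n_segments:
            raise InputError(
                f"cannot place {spec.n_coughs} coughs in {n_segments} segments "
                "without boundary straddling"
            )
        chosen = rng.choice(n_segments, size=spec.n_coughs, replace=False)
        for seg_idx, d in zip(np.sort(chosen), durations):
            margin = seg - d - 0.05
            if margin <= 0:
                raise InputError("event longer than a segment")
            starts.append(seg_idx * seg + 0.025 + rng.uniform(0, margin))
        return starts
    for d in durations:
        for _ in range(1000):
            s = rng.uniform(0, spec.duration_s - d)
            if all(s + d + 0.2 < a or a2 + 0.2 < s for a, a2 in
                   ((st, st + dd) for st, dd in zip(starts, durations))):
                starts.append(s)
                break
        else:
            raise InputError("could not place events without overlap")
    return sorted(starts)


def synth_background(spec: SceneSpec, sample_rate_hz: int = DEFAULT_SR,
                     seed_offset: int = 0) -> np.ndarray:
    """Unscaled background bed for a scene (babble/hum beds, slam events)."""
    rng = np.random.default_rng((spec.seed + seed_offset) % 2**31)
    n = int(round(spec.duration_s * sample_rate_hz))
    bed = np.zeros(n)
    if "babble" in spec.distractors:
        bed += synth_babble(spec.duration_s, sample_rate_hz,
                            seed=int(rng.integers(2**31))).samples[:n]
    if "hum" in spec.distractors:
        bed += synth_hum(spec.duration_s, sample_rate_hz,
                         seed=int(rng.integers(2**31))).samples[:n]
    if not spec.distractors:
        bed += 1e-3 * rng.standard_normal(n)  # sensor noise floor
    if "door_slam" in spec.distractors:
        n_slams = max(1, int(round(spec.duration_s / 60.0 * spec.slam_rate_per_min)))
        for _ in range(n_slams):
            slam = synth_door_slam(sample_rate_hz, seed=int(rng.integers(2**31)))
            start = int(rng.uniform(0, max(1, n - len(slam.samples))))
            seg = bed[start:start + len(slam.samples)]
            seg += slam.samples[:len(seg)] * 2.0  # slams stand out of the bed
    return bed


def synth_scene(spec: SceneSpec,
                sample_rate_hz: int = DEFAULT_SR) -> Tuple[AudioRecording, EventLabelSet]:
    """Generate a labelled scene: coughs mixed over the background bed.

    The background is scaled so that the mean per-event cough power over
    its labelled interval exceeds the background bed power by
    ``spec.snr_db`` decibels; each cough's interval power is normalized
    to the same reference, so per-event SNR is uniform.  Labels are the
    exact placement intervals.
    """
    rng = np.random.default_rng(spec.seed % 2**31)
    clips: List[np.ndarray] = []
    durations: List[float] = []
    for _ in range(spec.n_coughs):
        p = _sample_cough_params(rng)
        clip = synth_cough(p, sample_rate_hz, seed=int(rng.integers(2**31))).samples
        clips.append(clip)
        durations.append(len(clip) / sample_rate_hz)
    starts = _place_events(rng, spec, durations)
    n = int(round(spec.duration_s * sample_rate_hz))
    fg = np.zeros(n)
    labels = []
    p_ref = 0.01  # reference mean cough power over its interval
    for s, clip in zip(starts, clips):
        power = float(np.mean(clip ** 2))
        clip = clip * np.sqrt(p_ref / power)
        i0 = int(round(s * sample_rate_hz))
        i1 = min(i0 + len(clip), n)
        fg[i0:i1] += clip[: i1 - i0]
        labels.append((s, s + (i1 - i0) / sample_rate_hz))
    bed = synth_background(spec, sample_rate_hz, seed_offset=1)
    bed_power = float(np.mean(bed ** 2))
    if bed_power > 0:
        target = p_ref / (10.0 ** (spec.snr_db / 10.0))
        bed = bed * np.sqrt(target / bed_power)
    mix = np.clip(fg + bed, -1.0, 1.0)
    return (AudioRecording(mix, sample_rate_hz),
            EventLabelSet(labels, spec.duration_s))


def sample_hmm_sequences(model: Hmm, n: int, length: int,
                         seed: int = 0) -> List[FeatureVectorSequence]:
    """Draw feature sequences from an HMM's joint distribution.

    State dynamics follow the model's full transition law including the
    exit pseudo-state: a sequence ends when exit is drawn, with
    ``length`` acting as a frame cap.  Seeded and deterministic.
    """
    rng = np.random.default_rng(seed)
    n_states = model.n_states
    # successor probabilities over [states..., exit]
    rows = np.exp(np.column_stack([model.log_A, model.log_exit]))
    rows = rows / rows.sum(axis=1, keepdims=True)
    pi = np.exp(model.log_pi)
    out = []
    for _ in range(n):
        frames = []
        state = int(rng.choice(n_states, p=pi / pi.sum()))
        for _t in range(length):
            em = model.emissions[state]
            m = int(rng.choice(em.n_mix, p=em.weights))
            frames.append(rng.normal(em.means[m], np.sqrt(em.variances[m])))
            nxt = int(rng.choice(n_states + 1, p=rows[state]))
            if nxt == n_states:  # exit drawn
                break
            state = nxt
        X = np.asarray(frames)
        out.append(FeatureVectorSequence(X, np.arange(len(X)) * 0.01, "sampled"))
    return out


def synth_accel(duration_s: float, event_times: Sequence[float],
                coupling: float = 0.0, seed: int = 0) -> AccelerometerTrace:
    """Per-minute activity scores positively coupled to cough events.

    The baseline emulates mostly-sedentary wear: zero most minutes with
    occasional activity bouts (marginal mean ~0.8, SD ~2.9 on the 0-24
    scale).  Each cough in a minute adds ``coupling`` to that minute's
    score; scores are capped at 24.
    """
    for t in event_times:
        if not 0 <= t <= duration_s:
            raise InputError("event time outside trace duration")
    rng = np.random.default_rng(seed)
    n_min = int(duration_s // 60)
    active = rng.random(n_min) < 0.15
    bouts = rng.gamma(shape=1.2, scale=4.6, size=n_min)
    scores = np.where(active, bouts, 0.0)
    counts = np.bincount(
        (np.asarray(event_times, dtype=float) // 60).astype(int).clip(0, max(n_min - 1, 0)),
        minlength=n_min,
    )[:n_min] if n_min else np.zeros(0)
    scores = np.minimum(scores + coupling * counts, SCALE_MAX)
    return AccelerometerTrace(minute_scores=scores)


def _likert_cutpoints(favorability: float) -> np.ndarray:
    """Latent-normal cutpoints for the 5 response categories."""
    return norm.ppf([0.2, 0.4, 0.6, 0.8]) - favorability


def _discretization_attenuation(cutpoints: np.ndarray) -> float:
    """Pearson-correlation attenuation factor of thresholding a standard
    normal at the given cutpoints (per margin)."""
    edges = np.concatenate([[-np.inf], cutpoints, [np.inf]])
    probs = np.diff(norm.cdf(edges))
    values = np.arange(1, len(probs) + 1, dtype=float)
    mean = (probs * values).sum()
    sd = np.sqrt((probs * (values - mean) ** 2).sum())
    cov = norm.pdf(cutpoints).sum()  # Cov(discretized, latent)
    return cov / sd


def synth_survey(n: int, k: int = N_SURVEY_ITEMS, rho: float = 0.33,
                 seed: int = 0, favorability: float = 0.0) -> List[SurveyResponse]:
    """Simulate survey responses under a parallel-items model.

    Each respondent has a latent acceptance score; each item adds
    independent noise, then is discretized to 1..5.  The latent
    inter-item correlation is inflated by the analytic discretization
    attenuation so the *observed* items have inter-item correlation
    close to ``rho``.  ``favorability`` shifts responses toward
    agreement (in latent SD units).
    """
    if not 0 <= rho < 1:
        raise InputError("rho must be in [0, 1)")
    if k != N_SURVEY_ITEMS:
        raise InputError(f"survey instrument has exactly {N_SURVEY_ITEMS} items")
    rng = np.random.default_rng(seed)
    cuts = _likert_cutpoints(favorability)
    lam = _discretization_attenuation(cuts)
    rho_latent = min(rho / lam ** 2, 0.999)
    z = rng.standard_normal(n)
    eps = rng.standard_normal((n, k))
    latent = np.sqrt(rho_latent) * z[:, None] + np.sqrt(1 - rho_latent) * eps
    items = 1 + (latent[..., None] > cuts).sum(axis=-1)
    return [
        SurveyResponse(f"r{i:04d}", [int(v) for v in items[i]])
        for i in range(n)
    ]
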