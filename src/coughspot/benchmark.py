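"""End-to-end detector benchmark on synthetic scenes.

Builds the seeded training corpus (cough clips plus background /
door-slam / near-silence filler clips, all sliced from 6-second scene
segments so training features are normalized exactly like deployment
features), trains the default recognition network, and measures
sensitivity on cough-bearing scenes and false alarms per hour on
cough-free distractor audio.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np

from .audio import AudioRecording, segment_stream
from .detection import DetectionConfig, detect_events, events_from_results
from .features import FeatureConfig, features_for_segment
from .hmm import Hmm, train_hmm
from .metrics import MatchResult, fp_per_hour, match_events, sensitivity
from .network import RecognitionNetwork
from .synthetic import (
    SceneSpec,
    synth_babble,
    synth_door_slam,
    synth_hum,
    synth_scene,
)

DEFAULT_SNR_DB = 10.0
_P_REF = 0.01  # reference cough interval power used by synth_scene


def _slice_frames(fv, t0: float, t1: float):
    """Frames whose start times fall in [t0, t1)."""
    sel = (fv.frame_times_s >= t0) & (fv.frame_times_s < t1)
    from .features import FeatureVectorSequence

    return FeatureVectorSequence(fv.vectors[sel], fv.frame_times_s[sel], fv.config_id)


def _segment_features(rec: AudioRecording, cfg: FeatureConfig):
    segs = list(segment_stream(rec))
    return [features_for_segment(s, cfg) for s in segs]


def training_corpus(seed: int, n_cough: int = 200, n_background: int = 200,
                    snr_db: float = DEFAULT_SNR_DB,
                    feature_cfg: FeatureConfig = FeatureConfig()) -> Dict[str, list]:
    """Labelled feature-sequence corpus for training the network.

    Cough sequences are sliced (with 50 ms context) from 6-s one-cough
    scenes; the background allotment is split into babble+hum clips,
    door-slam clips and a few near-silence clips so the fillers cover
    the full distractor repertoire.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed % 2**31)
    sr = feature_cfg.sample_rate_hz
    corpus: Dict[str, list] = {"cough": [], "background": [], "door_slam": []}
    # -- cough clips --
    made = 0
    while made < n_cough:
        spec = SceneSpec(duration_s=6.0, n_coughs=1, snr_db=snr_db,
                         distractors=("babble", "hum"),
                         seed=int(rng.integers(2**31)))
        rec, labels = synth_scene(spec, sr)
        fv = _segment_features(rec, feature_cfg)[0]
        t0, t1 = labels.events[0]
        clip = _slice_frames(fv, t0 - 0.05, t1 + 0.05)
        if clip.n_frames >= 8:
            corpus["cough"].append(clip)
            made += 1
    # -- background allotment: babble+hum, door slams, near silence --
    n_slam = max(1, n_background // 5)
    n_silence = max(1, n_background // 10)
    n_bed = n_background - n_slam - n_silence
    target_bed_power = _P_REF / (10.0 ** (snr_db / 10.0))
    for _ in range(n_bed):
        spec = SceneSpec(duration_s=6.0, n_coughs=0, snr_db=snr_db,
                         distractors=("babble", "hum"),
                         seed=int(rng.integers(2**31)))
        rec, _ = synth_scene(spec, sr)
        fv = _segment_features(rec, feature_cfg)[0]
        start = float(rng.uniform(0.0, 4.5))
        corpus["background"].append(_slice_frames(fv, start, start + 1.0))
    for i in range(n_silence):
        # quiet audio coverage: sensor-level noise and exact digital
        # silence (whose features sit at the energy floor)
        if i % 2 == 0:
            quiet = AudioRecording(1e-4 * rng.standard_normal(int(6.0 * sr)), sr)
        else:
            quiet = AudioRecording(np.zeros(int(6.0 * sr)), sr)
        fv = _segment_features(quiet, feature_cfg)[0]
        corpus["background"].append(_slice_frames(fv, 1.0, 2.0))
    for _ in range(n_slam):
        s1, s2, s3 = (int(rng.integers(2**31)) for _ in range(3))
        bed = (synth_babble(6.0, sr, s1).samples
               + synth_hum(6.0, sr, s2).samples)
        scale = np.sqrt(target_bed_power / np.mean(bed ** 2))
        slam = synth_door_slam(sr, s3).samples * 2.0
        pos = int(2.5 * sr)
        mix = bed.copy()
        mix[pos:pos + len(slam)] += slam[: len(mix) - pos]
        rec = AudioRecording(np.clip(mix * scale, -1, 1), sr)
        fv = _segment_features(rec, feature_cfg)[0]
        corpus["door_slam"].append(
            _slice_frames(fv, 2.45, 2.5 + len(slam) / sr + 0.05))
    return corpus


def train_default_network(seed: int, n_cough: int = 200, n_background: int = 200,
                          snr_db: float = DEFAULT_SNR_DB,
                          feature_cfg: FeatureConfig = FeatureConfig(),
                          loop_penalty: float = 0.0,
                          cough_states: int = 5, filler_states: int = 3,
                          n_mix: int = 2) -> RecognitionNetwork:
    """Train the default cough + filler recognition network."""
    corpus = training_corpus(seed, n_cough, n_background, snr_db, feature_cfg)
    models: List[Hmm] = [
        train_hmm("cough", corpus["cough"], cough_states, n_mix, seed=seed),
        train_hmm("background", corpus["background"], filler_states, n_mix, seed=seed),
        train_hmm("door_slam", corpus["door_slam"], filler_states, n_mix, seed=seed),
    ]
    return RecognitionNetwork(models, loop_penalty=loop_penalty)


def sensitivity_benchmark(net: RecognitionNetwork, scene_seeds: Sequence[int],
                          n_coughs: int = 30, duration_s: float = 600.0,
                          snr_db: float = DEFAULT_SNR_DB, tol_s: float = 0.5,
                          detection_cfg: Optional[DetectionConfig] = None,
                          feature_cfg: FeatureConfig = FeatureConfig()) -> dict:
    """Detect on cough-bearing scenes and score against generator truth."""
    cfg = detection_cfg or DetectionConfig()
    per_seed = []
    total_tp = total_fn = total_fp = 0
    for s in scene_seeds:
        spec = SceneSpec(duration_s=duration_s, n_coughs=n_coughs,
                         snr_db=snr_db, distractors=("babble", "hum"), seed=s)
        rec, truth = synth_scene(spec, feature_cfg.sample_rate_hz)
        results = detect_events(rec, net, cfg, feature_cfg)
        m = match_events(events_from_results(results), truth, tol_s)
        per_seed.append({"seed": s, "tp": m.tp, "fn": m.fn, "fp": m.fp,
                         "sensitivity": sensitivity(m)})
        total_tp += m.tp
        total_fn += m.fn
        total_fp += m.fp
    return {
        "per_seed": per_seed,
        "mean_sensitivity": float(np.mean([p["sensitivity"] for p in per_seed])),
        "total_tp": total_tp,
        "n_truth": total_tp + total_fn,
        "total_fp": total_fp,
    }


def false_alarm_benchmark(net: RecognitionNetwork, scene_seeds: Sequence[int],
                          duration_s: float = 720.0,
                          snr_db: float = DEFAULT_SNR_DB,
                          detection_cfg: Optional[DetectionConfig] = None,
                          feature_cfg: FeatureConfig = FeatureConfig()) -> dict:
    """Detect on cough-free distractor scenes; every event is a false
    positive."""
    cfg = detection_cfg or DetectionConfig()
    per_seed = []
    for s in scene_seeds:
        spec = SceneSpec(duration_s=duration_s, n_coughs=0, snr_db=snr_db,
                         distractors=("babble", "hum", "door_slam"), seed=s)
        rec, _ = synth_scene(spec, feature_cfg.sample_rate_hz)
        results = detect_events(rec, net, cfg, feature_cfg)
        n_fp = len(events_from_results(results))
        m = MatchResult(tp=0, fn=0, fp=n_fp)
        per_seed.append({"seed": s, "fp": n_fp,
                         "fp_per_hour": fp_per_hour(m, duration_s)})
    return {
        "per_seed": per_seed,
        "mean_fp_per_hour": float(np.mean([p["fp_per_hour"] for p in per_seed])),
        "total_hours": len(scene_seeds) * duration_s / 3600.0,
    }
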