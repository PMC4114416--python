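"""Cepstral feature extraction for the cough detector.

Per-frame descriptive feature vectors follow the standard automatic
speech recognition recipe: pre-emphasis, Hamming window, mel filterbank,
log compression, DCT-II cepstra with the zeroth coefficient replaced by
log frame energy, plus delta and delta-delta dynamics.  Cepstral mean
normalization (CMN) is applied per processing segment to the cepstral
coefficients only — log-energy is left raw because the absolute level of
an impulsive cough relative to the background bed is itself a cue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft

from .audio import AudioRecording, FrameSequence, Segment, frame_signal
from .errors import InputError


@dataclass(frozen=True)
class FeatureConfig:
    """Front-end configuration.

    Attributes
    ----------
    sample_rate_hz : working sample rate the frames are assumed to be at.
    frame_s, hop_s : frame geometry in seconds (25 ms / 10 ms defaults).
    n_mel : number of triangular mel filters.
    n_cepstra : static cepstral coefficients kept (c0 replaced by log-energy).
    use_deltas : append delta and delta-delta dynamics (D = 3 * n_cepstra).
    preemphasis : first-order pre-emphasis coefficient.
    cmn : subtract the per-sequence mean of each cepstral coefficient
        (energy column excluded).
    energy_floor : lower clamp applied inside every log, keeping silent
        frames finite.
    """

    sample_rate_hz: int = 16000
    frame_s: float = 0.025
    hop_s: float = 0.010
    n_mel: int = 26
    n_cepstra: int = 13
    use_deltas: bool = True
    preemphasis: float = 0.97
    cmn: bool = True
    n_fft: int = 512
    energy_floor: float = 1e-10
    delta_window: int = 2
    fmin_hz: float = 0.0
    fmax_hz: Optional[float] = None

    @property
    def n_features(self) -> int:
        return self.n_cepstra * (3 if self.use_deltas else 1)

    @property
    def config_id(self) -> str:
        return (
            f"mfcc{self.n_cepstra}x{3 if self.use_deltas else 1}"
            f"_sr{self.sample_rate_hz}_mel{self.n_mel}"
            f"_cmn{int(self.cmn)}"
        )


@dataclass
class FeatureVectorSequence:
    """A T x D matrix of per-frame feature vectors with frame start times."""

    vectors: np.ndarray
    frame_times_s: np.ndarray
    config_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_features(self) -> int:
        return self.vectors.shape[1]

    def to_csv(self, path) -> None:
        n_static = self.n_features // 3 if self.n_features % 3 == 0 else self.n_features
        names = [f"c{i}" for i in range(n_static)]
        if n_static * 3 == self.n_features:
            names += [f"d{i}" for i in range(n_static)] + [f"dd{i}" for i in range(n_static)]
        df = pd.DataFrame(self.vectors, columns=names[: self.n_features])
        df.insert(0, "time_s", self.frame_times_s)
        df.to_csv(path, index=False)


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(cfg: FeatureConfig) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mel, n_fft//2 + 1)."""
    fmax = cfg.fmax_hz if cfg.fmax_hz is not None else cfg.sample_rate_hz / 2.0
    mel_pts = np.linspace(_hz_to_mel(cfg.fmin_hz), _hz_to_mel(fmax), cfg.n_mel + 2)
    hz_pts = _mel_to_hz(mel_pts)
    bins = np.floor((cfg.n_fft + 1) * hz_pts / cfg.sample_rate_hz).astype(int)
    fb = np.zeros((cfg.n_mel, cfg.n_fft // 2 + 1))
    for m in range(1, cfg.n_mel + 1):
        lo, mid, hi = bins[m - 1], bins[m], bins[m + 1]
        for k in range(lo, mid):
            if mid > lo:
                fb[m - 1, k] = (k - lo) / (mid - lo)
        for k in range(mid, hi):
            if hi > mid:
                fb[m - 1, k] = (hi - k) / (hi - mid)
    return fb


def _deltas(x: np.ndarray, window: int) -> np.ndarray:
    """Regression deltas over +/- window frames, edges replicated."""
    T = x.shape[0]
    denom = 2.0 * sum(k * k for k in range(1, window + 1))
    padded = np.concatenate([np.repeat(x[:1], window, axis=0), x,
                             np.repeat(x[-1:], window, axis=0)])
    out = np.zeros_like(x)
    for k in range(1, window + 1):
        out += k * (padded[window + k:window + k + T] - padded[window - k:window - k + T])
    return out / denom


def compute_feature_vectors(frames: FrameSequence, cfg: FeatureConfig) -> FeatureVectorSequence:
    """Compute the T x D cepstral feature matrix for a frame sequence.

    Deterministic for fixed input and configuration.  Raises
    :class:`InputError` on non-finite samples.
    """
    X = frames.frames
    if X.size and not np.all(np.isfinite(X)):
        raise InputError("non-finite samples in frame sequence")
    T = X.shape[0]
    if T == 0:
        return FeatureVectorSequence(
            np.empty((0, cfg.n_features)), np.empty(0), cfg.config_id
        )
    # per-frame pre-emphasis; the first sample is attenuated consistently
    Y = np.empty_like(X)
    Y[:, 0] = X[:, 0] * (1.0 - cfg.preemphasis)
    Y[:, 1:] = X[:, 1:] - cfg.preemphasis * X[:, :-1]
    win = np.hamming(X.shape[1])
    Yw = Y * win
    spec = rfft(Yw, n=cfg.n_fft, axis=1)
    power = (np.abs(spec) ** 2) / cfg.n_fft
    fb = mel_filterbank(cfg)
    fbank = power @ fb.T
    log_fbank = np.log(np.maximum(fbank, cfg.energy_floor))
    cep = dct(log_fbank, type=2, norm="ortho", axis=1)[:, : cfg.n_cepstra]
    log_energy = np.log(np.maximum(np.sum(power, axis=1), cfg.energy_floor))
    cep[:, 0] = log_energy
    if cfg.cmn and T > 0:
        cep[:, 1:] = cep[:, 1:] - cep[:, 1:].mean(axis=0, keepdims=True)
    if cfg.use_deltas:
        d = _deltas(cep, cfg.delta_window)
        dd = _deltas(d, cfg.delta_window)
        feats = np.concatenate([cep, d, dd], axis=1)
    else:
        feats = cep
    return FeatureVectorSequence(feats, frames.frame_times_s, cfg.config_id)


def features_for_segment(seg: Segment, cfg: FeatureConfig) -> FeatureVectorSequence:
    """Frame one processing segment and compute its features (CMN local)."""
    rec = AudioRecording(seg.samples, cfg.sample_rate_hz)
    frames = frame_signal(rec, cfg.frame_s, cfg.hop_s)
    fv = compute_feature_vectors(frames, cfg)
    fv.frame_times_s = fv.frame_times_s + seg.start_s
    return fv
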