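"""Audio containers, WAV I/O, framing and 6-second segmentation.

The monitoring pipeline works on single-channel amplitude streams in
[-1, 1].  Recordings are cut into fixed-length analysis frames (model
inputs, trailing partial frame dropped) and into 6-second segments
(processing containers, trailing partial segment kept), mirroring the
block-wise operation of a wearable monitor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import DegenerateInputError, InputError

DEFAULT_SEGMENT_S = 6.0


@dataclass
class AudioRecording:
    """A mono amplitude stream with its sample rate and optional start time.

    Parameters
    ----------
    samples : ndarray
        Float amplitudes in [-1, 1].
    sample_rate_hz : int
        Sampling rate in samples/second.
    start_time : float, optional
        Recording start as seconds since the Unix epoch.  When present,
        hourly aggregation and daily reports align to wall-clock hours.
    """

    samples: np.ndarray
    sample_rate_hz: int
    start_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InputError("AudioRecording samples must be one-dimensional")
        if self.sample_rate_hz <= 0:
            raise InputError("sample_rate_hz must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise InputError("AudioRecording samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz

    def normalized(self) -> "AudioRecording":
        """Return a copy rescaled so that peak amplitude is at most 1."""
        peak = float(np.max(np.abs(self.samples))) if self.samples.size else 0.0
        if peak <= 1.0:
            return AudioRecording(self.samples.copy(), self.sample_rate_hz, self.start_time)
        return AudioRecording(self.samples / peak, self.sample_rate_hz, self.start_time)


@dataclass
class FrameSequence:
    """Fixed-length, fixed-hop analysis frames cut from a recording."""

    frames: np.ndarray  # (T, L)
    frame_length_samples: int
    hop_samples: int
    sample_rate_hz: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_times_s(self) -> np.ndarray:
        """Start offset of each frame, in seconds."""
        return np.arange(self.n_frames) * (self.hop_samples / self.sample_rate_hz)


@dataclass
class Segment:
    """One processing block (default 6 s) of a recording."""

    index: int
    start_s: float
    duration_s: float
    samples: np.ndarray = field(repr=False)


def read_wav(path, target_rate_hz: Optional[int] = None) -> AudioRecording:
    """Read a PCM or float WAV file as a mono recording in [-1, 1].

    Multi-channel files are mean-downmixed.  If ``target_rate_hz`` differs
    from the file's rate the signal is resampled with a polyphase
    anti-aliasing filter.
    """
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises ValueError on corrupt files
        raise InputError(f"unreadable WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise DegenerateInputError(f"zero-length audio in {path!r}")
    data = np.asarray(data)
    dtype = data.dtype
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        scale = float(max(abs(info.min), info.max))
        offset = 0.0
        if info.min == 0:  # unsigned PCM (e.g. uint8) is offset-binary
            offset = (info.max + 1) / 2.0
            scale = offset
        data = (data.astype(np.float64) - offset) / scale
    else:
        data = data.astype(np.float64)
    data = np.clip(data, -1.0, 1.0)
    if target_rate_hz is not None and target_rate_hz != rate:
        g = math.gcd(int(target_rate_hz), int(rate))
        data = resample_poly(data, target_rate_hz // g, rate // g)
        data = np.clip(data, -1.0, 1.0)
        rate = target_rate_hz
    return AudioRecording(data, int(rate))


def write_wav(path, rec: AudioRecording, pcm16: bool = True) -> None:
    """Write a recording as 16-bit PCM (default) or float32 WAV."""
    x = np.clip(rec.samples, -1.0, 1.0)
    if pcm16:
        wavfile.write(path, rec.sample_rate_hz, (x * 32767.0).astype(np.int16))
    else:
        wavfile.write(path, rec.sample_rate_hz, x.astype(np.float32))


def frame_signal(rec: AudioRecording, frame_length_s: float, hop_s: float) -> FrameSequence:
    """Cut a recording into overlapping fixed-length frames.

    The frame count is ``1 + floor((N - L)/H)`` for N >= L and zero
    otherwise; a trailing partial frame is dropped.
    """
    if not (frame_length_s >= hop_s > 0):
        raise InputError("require frame_length_s >= hop_s > 0")
    L = int(round(frame_length_s * rec.sample_rate_hz))
    H = int(round(hop_s * rec.sample_rate_hz))
    n = len(rec.samples)
    if n < L:
        frames = np.empty((0, L), dtype=np.float64)
    else:
        frames = sliding_window_view(rec.samples, L)[::H].copy()
    return FrameSequence(frames, L, H, rec.sample_rate_hz)


def segment_stream(rec: AudioRecording, segment_s: float = DEFAULT_SEGMENT_S) -> Iterator[Segment]:
    """Tile a recording into ordered, non-overlapping segments.

    All segments have duration ``segment_s`` except possibly the last,
    which may be shorter; together they cover the recording exactly.
    """
    if segment_s <= 0:
        raise InputError("segment_s must be positive")
    step = int(round(segment_s * rec.sample_rate_hz))
    n = len(rec.samples)
    index = 0
    for start in range(0, n, step):
        chunk = rec.samples[start:start + step]
        yield Segment(
            index=index,
            start_s=start / rec.sample_rate_hz,
            duration_s=len(chunk) / rec.sample_rate_hz,
            samples=chunk,
        )
        index += 1
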