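"""Segment-wise cough event detection, audit retention, hourly counts.

A recording is processed in independent 6-second blocks, mirroring a
wearable monitor's block pipeline: features are computed per segment
(with segment-local cepstral mean normalization), decoded against the
recognition network, and cough-labelled spans become timestamped
events.  Every segment containing an event is retained for audit;
event-free segments are retained at random with a configurable
probability, which is what later allows sensitivity *and* specificity
to be estimated from the archived audio alone.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .audio import AudioRecording, segment_stream, write_wav
from .errors import ConfigurationError, InputError
from .features import FeatureConfig, features_for_segment
from .network import RecognitionNetwork, _FlatNetwork
from . import network as _network_mod


@dataclass
class CoughEvent:
    """A detected cough: a time interval within the recording."""

    start_s: float
    end_s: float
    segment_index: int
    log_score: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise InputError("CoughEvent requires end_s > start_s")

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass
class SegmentResult:
    """Per-segment detection outcome and audit-retention flag."""

    segment_index: int
    events: List[CoughEvent]
    retained: bool
    retention_reason: str  # "positive" | "random" | "none"


@dataclass
class DetectionConfig:
    """Detector knobs.

    ``min_event_s`` drops decoded cough spans shorter than a plausible
    cough phase; ``merge_gap_s`` fuses spans separated by less than a
    breath pause; ``retention_probability`` is the chance an event-free
    segment is archived for audit.
    """

    segment_s: float = 6.0
    min_event_s: float = 0.06
    merge_gap_s: float = 0.2
    retention_probability: float = 0.05
    seed: int = 0
    loop_penalty: Optional[float] = None  # overrides the network's value

    def __post_init__(self) -> None:
        if not 0.0 <= self.retention_probability <= 1.0:
            raise InputError("retention_probability must be in [0, 1]")
        if self.min_event_s < 0:
            raise InputError("min_event_s must be >= 0")


@dataclass
class HourlyCounts:
    hour_start: float  # seconds since epoch, or seconds from recording start
    cough_count: int
    monitored_fraction: float


def _spans_to_events(spans, frame_times, frame_s, seg_index, cfg) -> List[CoughEvent]:
    """Convert decoded cough spans to merged, duration-filtered events."""
    raw = []
    for sp in spans:
        start = float(frame_times[sp.start_frame])
        end = float(frame_times[sp.end_frame - 1]) + frame_s
        raw.append([start, end, sp.log_score])
    raw.sort()
    merged: List[list] = []
    for start, end, score in raw:
        if merged and start - merged[-1][1] < cfg.merge_gap_s:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2] += score
        else:
            merged.append([start, end, score])
    return [
        CoughEvent(s, e, seg_index, sc)
        for s, e, sc in merged
        if e - s >= cfg.min_event_s
    ]


def apply_retention(results: Sequence[SegmentResult], retention_probability: float,
                    rng: np.random.Generator) -> None:
    """Set audit-retention flags in place.

    Segments with events are always retained (reason "positive");
    event-free segments are retained with the given probability
    (reason "random").
    """
    draws = rng.random(len(results))
    for r, u in zip(results, draws):
        if r.events:
            r.retained, r.retention_reason = True, "positive"
        elif u < retention_probability:
            r.retained, r.retention_reason = True, "random"
        else:
            r.retained, r.retention_reason = False, "none"


def detect_events(rec: AudioRecording, net: RecognitionNetwork,
                  cfg: DetectionConfig = DetectionConfig(),
                  feature_cfg: FeatureConfig = FeatureConfig()) -> List[SegmentResult]:
    """Run the keyword-spotting detector over a recording, per segment.

    Each 6-second segment is decoded in isolation; cough-labelled spans
    become :class:`CoughEvent` records timestamped from recording
    start.  Returns one :class:`SegmentResult` per segment with the
    audit-retention protocol applied (seeded, reproducible).
    """
    if not net.models:
        raise ConfigurationError("empty recognition network")
    if cfg.loop_penalty is not None and cfg.loop_penalty != net.loop_penalty:
        net = RecognitionNetwork(net.models, cfg.loop_penalty, net.target_label)
    _FlatNetwork(net)  # validates dimensions up front
    results: List[SegmentResult] = []
    for seg in segment_stream(rec, cfg.segment_s):
        fv = features_for_segment(seg, feature_cfg)
        events: List[CoughEvent] = []
        if fv.n_frames > 0:
            if fv.n_features != net.n_features:
                raise ConfigurationError(
                    "feature configuration does not match the trained network"
                )
            try:
                path = _network_mod.decode_token_passing(net, fv)
            except ConfigurationError:
                path = None  # segment shorter than every model topology
            if path is not None:
                events = _spans_to_events(
                    path.spans_for(net.target_label), fv.frame_times_s,
                    feature_cfg.frame_s, seg.index, cfg,
                )
        results.append(SegmentResult(seg.index, events, False, "none"))
    rng = np.random.default_rng(cfg.seed)
    apply_retention(results, cfg.retention_probability, rng)
    return results


def events_from_results(results: Sequence[SegmentResult]) -> List[CoughEvent]:
    return [ev for r in results for ev in r.events]


def aggregate_hourly(events: Sequence[CoughEvent], rec_start: Optional[float],
                     rec_duration_s: float) -> List[HourlyCounts]:
    """Bucket events into clock hours intersecting the recording.

    With ``rec_start`` (epoch seconds) buckets align to wall-clock
    hours; otherwise they are hours from recording start.  Counts
    partition the events by event start time; ``monitored_fraction`` is
    the covered share of each hour.
    """
    for ev in events:
        if ev.start_s < 0 or ev.start_s > rec_duration_s:
            raise InputError(f"event at {ev.start_s}s outside recording span")
    anchor = rec_start if rec_start is not None else 0.0
    first_hour = math.floor(anchor / 3600.0) * 3600.0
    out: List[HourlyCounts] = []
    h = first_hour
    while h < anchor + rec_duration_s:
        lo = max(h, anchor)
        hi = min(h + 3600.0, anchor + rec_duration_s)
        count = sum(1 for ev in events if lo <= anchor + ev.start_s < hi)
        out.append(HourlyCounts(h, count, (hi - lo) / 3600.0))
        h += 3600.0
    return out


def export_retained_audio(rec: AudioRecording, results: Sequence[SegmentResult],
                          out_dir, segment_s: float = 6.0) -> pd.DataFrame:
    """Write one WAV per retained segment plus a CSV manifest.

    Filenames encode segment index and retention reason; the manifest
    lists file, reason and event count, and is byte-identical across
    re-runs with the same inputs.
    """
    os.makedirs(out_dir, exist_ok=True)
    step = int(round(segment_s * rec.sample_rate_hz))
    rows = []
    for r in results:
        if not r.retained:
            continue
        name = f"segment_{r.segment_index:05d}_{r.retention_reason}.wav"
        chunk = rec.samples[r.segment_index * step:(r.segment_index + 1) * step]
        write_wav(os.path.join(out_dir, name),
                  AudioRecording(chunk, rec.sample_rate_hz))
        rows.append({
            "file": name,
            "segment_index": r.segment_index,
            "reason": r.retention_reason,
            "n_events": len(r.events),
        })
    manifest = pd.DataFrame(rows, columns=["file", "segment_index", "reason", "n_events"])
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest


def events_to_csv(events: Sequence[CoughEvent], path) -> None:
    pd.DataFrame(
        [{"start_s": e.start_s, "end_s": e.end_s,
          "segment": e.segment_index, "score": e.log_score} for e in events],
        columns=["start_s", "end_s", "segment", "score"],
    ).to_csv(path, index=False)


def events_from_csv(path) -> List[CoughEvent]:
    df = pd.read_csv(path)
    return [
        CoughEvent(float(r.start_s), float(r.end_s), int(r.segment), float(r.score))
        for r in df.itertuples()
    ]


def hourly_to_csv(buckets: Sequence[HourlyCounts], path) -> None:
    pd.DataFrame(
        [{"hour_start": b.hour_start, "cough_count": b.cough_count,
          "monitored_fraction": b.monitored_fraction} for b in buckets],
        columns=["hour_start", "cough_count", "monitored_fraction"],
    ).to_csv(path, index=False)
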