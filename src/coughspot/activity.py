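"""Accelerometer activity scoring on the monitor's 0-24 scale.

The per-minute activity score is the mean absolute deviation (MAD) of
the acceleration magnitude within the minute, scaled so that a
sustained 1 g oscillation maps to the top of the scale, and capped at
24.  For a sinusoidal magnitude of amplitude A the MAD is 2A/pi, so the
calibration constant is 24 / (2/pi) = 12*pi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, UndefinedMetricError

SCALE_MAX = 24.0
CALIBRATION = 12.0 * np.pi  # maps MAD of a 1 g sinusoid (2/pi) to 24


@dataclass
class AccelerometerTrace:
    """Raw triaxial samples or pre-scored per-minute activity.

    Exactly one of the two representations is populated: raw mode
    carries (timestamps, ax, ay, az) in g units; scored mode carries
    one activity score in [0, 24] per minute.
    """

    timestamps: Optional[np.ndarray] = None
    ax: Optional[np.ndarray] = None
    ay: Optional[np.ndarray] = None
    az: Optional[np.ndarray] = None
    minute_scores: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.minute_scores is not None:
            self.minute_scores = np.asarray(self.minute_scores, dtype=np.float64)
            if self.minute_scores.size and (
                self.minute_scores.min() < 0 or self.minute_scores.max() > SCALE_MAX
            ):
                raise InputError("scored-mode values must lie in [0, 24]")
        else:
            if self.timestamps is None:
                raise InputError("trace needs timestamps+axes or minute_scores")
            self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
            if np.any(np.diff(self.timestamps) <= 0):
                raise InputError("timestamps must be strictly increasing")
            self.ax = np.asarray(self.ax, dtype=np.float64)
            self.ay = np.asarray(self.ay, dtype=np.float64)
            self.az = np.asarray(self.az, dtype=np.float64)

    @property
    def mode(self) -> str:
        return "scored" if self.minute_scores is not None else "raw"


@dataclass
class ActivitySummary:
    """Per-minute scores with their hourly means."""

    minute_scores: np.ndarray
    hourly_means: np.ndarray


def _hourly_means(minute_scores: np.ndarray) -> np.ndarray:
    n_hours = int(np.ceil(len(minute_scores) / 60)) if len(minute_scores) else 0
    return np.array([
        minute_scores[h * 60:(h + 1) * 60].mean() for h in range(n_hours)
    ])


def score_minutes(trace: AccelerometerTrace, rate_hz: Optional[float] = None) -> ActivitySummary:
    """Score a raw trace minute by minute on the 0-24 scale.

    Each complete minute's score is ``min(24, 12*pi * MAD(|a|))`` where
    |a| is the acceleration magnitude; an incomplete trailing minute is
    dropped.  A perfectly still trace (constant gravity vector) scores
    zero everywhere.
    """
    if trace.mode == "scored":
        return ActivitySummary(trace.minute_scores.copy(),
                               _hourly_means(trace.minute_scores))
    t = trace.timestamps
    # each sample covers one sample period, so the trace spans up to
    # just past the last timestamp
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    span = t[-1] - t[0] + dt
    if span < 60.0:
        raise InputError("need at least one complete minute of data")
    mag = np.sqrt(trace.ax ** 2 + trace.ay ** 2 + trace.az ** 2)
    t0 = t[0]
    n_min = int(span / 60.0 + 1e-9)
    scores = np.empty(n_min)
    for k in range(n_min):
        sel = (t - t0 >= 60.0 * k) & (t - t0 < 60.0 * (k + 1))
        m = mag[sel]
        if m.size == 0:
            scores[k] = 0.0
            continue
        mad = np.abs(m - m.mean()).mean()
        scores[k] = min(SCALE_MAX, CALIBRATION * mad)
    return ActivitySummary(scores, _hourly_means(scores))


def correlate_cough_activity(cough_counts: Sequence[float],
                             activity: Sequence[float]) -> Tuple[float, float, int]:
    """Pearson correlation between paired cough counts and activity.

    Returns (r, two-sided p from the t transform, n).  Requires equal
    length, n >= 3 and nonzero variance in both series.
    """
    x = np.asarray(cough_counts, dtype=np.float64)
    y = np.asarray(activity, dtype=np.float64)
    if x.shape != y.shape:
        raise InputError("paired series must have equal length")
    n = len(x)
    if n < 3:
        raise InputError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n


def read_accel_csv(path) -> AccelerometerTrace:
    """Read either accelerometer CSV dialect.

    Raw: columns (t, ax, ay, az).  Scored: columns (minute_start, score).
    Lines starting with ``#`` (provenance stamps) are ignored.
    """
    df = pd.read_csv(path, comment="#")
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if {"t", "ax", "ay", "az"}.issubset(cols):
        return AccelerometerTrace(
            timestamps=df["t"].to_numpy(), ax=df["ax"].to_numpy(),
            ay=df["ay"].to_numpy(), az=df["az"].to_numpy(),
        )
    if {"minute_start", "score"}.issubset(cols):
        return AccelerometerTrace(minute_scores=df["score"].to_numpy())
    raise InputError("unrecognized accelerometer CSV header")


def summary_to_csv(summary: ActivitySummary, path) -> None:
    pd.DataFrame({
        "minute_start": np.arange(len(summary.minute_scores)) * 60.0,
        "score": summary.minute_scores,
    }).to_csv(path, index=False)
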