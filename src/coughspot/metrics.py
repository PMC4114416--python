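"""Detector validation metrics and acceptance-survey statistics.

Two families live here.  Event-level validation compares detected
cough events against ground-truth intervals by one-to-one midpoint
matching and derives sensitivity, false positives per monitored hour,
and rater percent agreement.  Survey statistics score the 7-item
acceptance instrument (5-point Likert, total 7-35, satisfaction cutoff
28), per-item agreement proportions, Cronbach's alpha, and item-
companion Pearson correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedMetricError

N_SURVEY_ITEMS = 7
LIKERT_MIN, LIKERT_MAX = 1, 5
DEFAULT_CUTOFF = 28
AGREE_THRESHOLD = 4  # "agree" pools responses of 4 and 5


@dataclass
class EventLabelSet:
    """Ground-truth event intervals within a monitored duration."""

    events: List[Tuple[float, float]]
    total_duration_s: float

    def __post_init__(self) -> None:
        evs = sorted((float(a), float(b)) for a, b in self.events)
        for a, b in evs:
            if not (0.0 <= a < b <= self.total_duration_s):
                raise InputError(f"truth interval ({a}, {b}) outside [0, duration]")
        for (a1, b1), (a2, b2) in zip(evs, evs[1:]):
            if a2 < b1:
                raise InputError("truth intervals overlap")
        self.events = evs


@dataclass
class MatchResult:
    """One-to-one matching outcome between detections and truth."""

    tp: int
    fn: int
    fp: int
    matched_pairs: List[Tuple[int, int]] = field(default_factory=list)


@dataclass
class SurveyResponse:
    """One respondent's 7 Likert items; missing values are None."""

    respondent_id: str
    items: List[Optional[int]]

    def __post_init__(self) -> None:
        if len(self.items) != N_SURVEY_ITEMS:
            raise InputError(
                f"respondent {self.respondent_id}: expected {N_SURVEY_ITEMS} items"
            )
        for v in self.items:
            if v is not None and not (LIKERT_MIN <= int(v) <= LIKERT_MAX):
                raise InputError(
                    f"respondent {self.respondent_id}: item value {v} outside 1..5"
                )

    @property
    def complete(self) -> bool:
        return all(v is not None for v in self.items)

    @property
    def total(self) -> Optional[int]:
        return sum(self.items) if self.complete else None


def _midpoints(intervals) -> np.ndarray:
    return np.array([(a + b) / 2.0 for a, b in intervals])


def match_events(detected, truth: EventLabelSet, tol_s: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching of detections to truth events.

    Detections are visited in time order; each claims the earliest
    still-unmatched truth event whose midpoint lies within ``tol_s`` of
    its own.  Because every compatibility window has the same width,
    this greedy rule attains the maximum one-to-one matching (the
    convex-bipartite greedy argument) while staying deterministic.
    Unclaimed detections are false positives, unclaimed truth events
    false negatives.
    """
    if tol_s < 0:
        raise InputError("tol_s must be >= 0")
    det_iv = sorted(
        (ev.start_s, ev.end_s) if hasattr(ev, "start_s") else (float(ev[0]), float(ev[1]))
        for ev in detected
    )
    det_mid = _midpoints(det_iv)
    tru_mid = _midpoints(truth.events)
    used = np.zeros(len(tru_mid), dtype=bool)
    pairs: List[Tuple[int, int]] = []
    for i, m in enumerate(det_mid):
        for j, tm in enumerate(tru_mid):
            if not used[j] and abs(tm - m) <= tol_s:
                used[j] = True
                pairs.append((i, j))
                break
    tp = len(pairs)
    return MatchResult(tp=tp, fn=len(tru_mid) - tp, fp=len(det_mid) - tp,
                       matched_pairs=pairs)


def sensitivity(m: MatchResult) -> float:
    """True-positive fraction tp / (tp + fn)."""
    if m.tp + m.fn == 0:
        raise UndefinedMetricError("sensitivity undefined with no truth events")
    return m.tp / (m.tp + m.fn)


def fp_per_hour(m: MatchResult, monitored_s: float) -> float:
    """False positives per monitored hour."""
    if monitored_s <= 0:
        raise InputError("monitored_s must be positive")
    return m.fp / (monitored_s / 3600.0)


def percent_agreement(n_agree: int, n_total: int) -> float:
    """Rater percent agreement, 100 * n_agree / n_total."""
    if n_total <= 0:
        raise InputError("n_total must be positive")
    if not 0 <= n_agree <= n_total:
        raise InputError("need 0 <= n_agree <= n_total")
    return 100.0 * n_agree / n_total


def score_survey(responses: Sequence[SurveyResponse],
                 cutoff: int = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Score the acceptance survey: totals, satisfaction flags, summary.

    Totals range 7-35; ``satisfied`` means total >= cutoff (default 28,
    i.e. at least "agree" on every item on average).  Incomplete
    responses get a null total and are excluded from the summary, which
    is attached as ``df.attrs["summary"]`` (n, mean, sd, proportion
    satisfied).
    """
    rows = []
    for r in responses:
        rows.append({
            "respondent_id": r.respondent_id,
            "total": r.total,
            "satisfied": (r.total >= cutoff) if r.total is not None else None,
        })
    df = pd.DataFrame(rows, columns=["respondent_id", "total", "satisfied"])
    totals = df["total"].dropna().astype(float)
    df.attrs["summary"] = {
        "n": int(totals.size),
        "mean": float(totals.mean()) if totals.size else math.nan,
        "sd": float(totals.std(ddof=1)) if totals.size > 1 else math.nan,
        "prop_satisfied": float(df["satisfied"].dropna().mean()) if totals.size else math.nan,
    }
    return df


def item_agreement(responses: Sequence[SurveyResponse]) -> pd.DataFrame:
    """Per-item proportion answering agree (4) or strongly agree (5).

    Missing values are excluded pairwise, so denominators can differ
    across items; an all-missing item yields a null proportion with a
    flag.
    """
    rows = []
    for k in range(N_SURVEY_ITEMS):
        vals = [r.items[k] for r in responses if r.items[k] is not None]
        n_missing = len(responses) - len(vals)
        if not vals:
            rows.append({"item": k + 1, "n_agree": 0, "n_valid": 0,
                         "n_missing": n_missing, "proportion": math.nan,
                         "undefined": True})
            continue
        n_agree = sum(1 for v in vals if v >= AGREE_THRESHOLD)
        rows.append({"item": k + 1, "n_agree": n_agree, "n_valid": len(vals),
                     "n_missing": n_missing,
                     "proportion": n_agree / len(vals), "undefined": False})
    return pd.DataFrame(rows)


def cronbach_alpha(items_matrix: np.ndarray) -> float:
    """Cronbach's alpha, k/(k-1) * (1 - sum(item var) / var(total)).

    Rows are respondents, columns items; rows with any missing value
    (NaN) are dropped listwise.  Unbiased (ddof=1) variances are used.
    """
    X = np.asarray(items_matrix, dtype=np.float64)
    if X.ndim != 2:
        raise InputError("items_matrix must be 2-D (respondents x items)")
    X = X[~np.isnan(X).any(axis=1)]
    n, k = X.shape
    if n < 2 or k < 2:
        raise InputError("need >= 2 complete responses and >= 2 items")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise UndefinedMetricError("alpha undefined: zero total-score variance")
    item_vars = X.var(axis=0, ddof=1)
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


def item_correlation(item_scores: Sequence[float],
                     companion_scores: Sequence[float]) -> Tuple[float, float, int]:
    """Pearson r between a survey item and a companion measure.

    Missing values (NaN) are dropped pairwise; shares the Pearson
    implementation used for the cough-activity correlation.
    """
    from .activity import correlate_cough_activity

    x = np.asarray(item_scores, dtype=np.float64)
    y = np.asarray(companion_scores, dtype=np.float64)
    if x.shape != y.shape:
        raise InputError("paired series must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return correlate_cough_activity(x[keep], y[keep])


def read_survey_csv(path) -> Tuple[List[SurveyResponse], pd.DataFrame]:
    """Read a survey CSV: respondent_id, item1..item7, companion columns.

    Blank cells are missing; ``#`` lines (provenance stamps) are
    ignored.  Returns the responses plus a DataFrame of any extra
    (companion) columns indexed like the input.
    """
    df = pd.read_csv(path, comment="#")
    item_cols = [f"item{i}" for i in range(1, N_SURVEY_ITEMS + 1)]
    missing_cols = [c for c in ["respondent_id"] + item_cols if c not in df.columns]
    if missing_cols:
        raise InputError(f"survey CSV missing columns: {missing_cols}")
    responses = []
    for _, row in df.iterrows():
        items = [None if pd.isna(row[c]) else int(row[c]) for c in item_cols]
        responses.append(SurveyResponse(str(row["respondent_id"]), items))
    companions = df.drop(columns=["respondent_id"] + item_cols)
    return responses, companions


def responses_to_matrix(responses: Sequence[SurveyResponse]) -> np.ndarray:
    """Stack responses into an n x 7 float matrix with NaN for missing."""
    return np.array([
        [np.nan if v is None else float(v) for v in r.items] for r in responses
    ])
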