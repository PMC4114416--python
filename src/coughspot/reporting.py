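"""Medication diary and the user-facing daily report.

The diary is an append-only line-delimited JSON store of medication
records (controller vs rescue) and free-text entries.  The daily
report assembles the hour-by-hour cough bar chart, the averaged
activity line, and medication marks for one calendar day, serializes
to stable JSON, and renders a chart image.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .activity import ActivitySummary
from .detection import CoughEvent, aggregate_hourly
from .errors import InputError

MEDICATION_KINDS = ("controller", "rescue")


@dataclass
class MedicationRecord:
    timestamp: float  # seconds since epoch
    kind: str
    note: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in MEDICATION_KINDS:
            raise InputError(f"unknown medication kind {self.kind!r}")


@dataclass
class DiaryEntry:
    timestamp: float
    text: str


class DiaryStore:
    """Append-only diary backed by an optional JSONL file."""

    def __init__(self, path=None):
        self.path = path
        self._records: List[dict] = []
        if path is not None and os.path.exists(path):
            with open(path) as fh:
                for line in fh:
                    if line.strip():
                        self._records.append(json.loads(line))

    def _append(self, rec: dict) -> None:
        self._records.append(rec)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")

    def log_medication(self, rec: MedicationRecord) -> "DiaryStore":
        self._append({"type": "medication", "timestamp": rec.timestamp,
                      "kind": rec.kind, "note": rec.note})
        return self

    def add_entry(self, entry: DiaryEntry) -> "DiaryStore":
        self._append({"type": "entry", "timestamp": entry.timestamp,
                      "text": entry.text})
        return self

    @staticmethod
    def _day_of(ts: float) -> str:
        return _dt.datetime.fromtimestamp(ts, _dt.timezone.utc).strftime("%Y-%m-%d")

    def medications_for_day(self, date: str) -> List[MedicationRecord]:
        return [
            MedicationRecord(r["timestamp"], r["kind"], r.get("note"))
            for r in self._records
            if r["type"] == "medication" and self._day_of(r["timestamp"]) == date
        ]

    def entries_for_day(self, date: str) -> List[DiaryEntry]:
        return [
            DiaryEntry(r["timestamp"], r["text"])
            for r in self._records
            if r["type"] == "entry" and self._day_of(r["timestamp"]) == date
        ]

    def summary_for_day(self, date: str) -> dict:
        meds = self.medications_for_day(date)
        return {k: sum(1 for m in meds if m.kind == k) for k in MEDICATION_KINDS}


@dataclass
class DailyReport:
    """One day's aligned hourly cough counts, activity means and marks."""

    date: str
    hourly_cough_counts: List[int]
    hourly_activity_means: List[float]
    medication_events: List[dict]
    diary_entries: List[dict]
    empty: bool = False

    def to_json(self) -> str:
        return json.dumps({
            "date": self.date,
            "empty": self.empty,
            "hourly_cough_counts": self.hourly_cough_counts,
            "hourly_activity_means": self.hourly_activity_means,
            "medication_events": self.medication_events,
            "diary_entries": self.diary_entries,
        }, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DailyReport":
        d = json.loads(text)
        return cls(
            date=d["date"],
            hourly_cough_counts=d["hourly_cough_counts"],
            hourly_activity_means=d["hourly_activity_means"],
            medication_events=d["medication_events"],
            diary_entries=d["diary_entries"],
            empty=d["empty"],
        )

    def render_chart(self, path) -> None:
        """Bar chart of hourly coughs with the activity line and
        medication marks overlaid."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        hours = np.arange(24)
        fig, ax = plt.subplots(figsize=(9, 4))
        ax.bar(hours, self.hourly_cough_counts, color="#4477aa", label="coughs/hour")
        ax.set_xlabel("hour of day")
        ax.set_ylabel("cough count")
        ax2 = ax.twinx()
        ax2.plot(hours, self.hourly_activity_means, color="#cc6644",
                 marker="o", label="mean activity")
        ax2.set_ylabel("activity (0-24)")
        ax2.set_ylim(0, 24)
        for m in self.medication_events:
            ts = _dt.datetime.fromtimestamp(m["timestamp"], _dt.timezone.utc)
            style = "--" if m["kind"] == "controller" else ":"
            ax.axvline(ts.hour + ts.minute / 60.0, color="green", linestyle=style)
        ax.set_title(f"Daily symptom report {self.date}")
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)


def build_report(events: Sequence[CoughEvent], activity: ActivitySummary,
                 diary: DiaryStore, date: str, recording_start: float,
                 recording_duration_s: float) -> DailyReport:
    """Assemble the daily report for one calendar date (UTC).

    Hourly cough bars come from :func:`aggregate_hourly`; activity
    means are the summary's hourly means aligned to the recording
    start; hours without monitored time are zero.  A date with no
    monitored overlap yields an empty-flagged report, not an error.
    """
    day_start = _dt.datetime.strptime(date, "%Y-%m-%d").replace(
        tzinfo=_dt.timezone.utc).timestamp()
    day_end = day_start + 24 * 3600.0
    counts = [0] * 24
    act = [0.0] * 24
    overlap = (recording_start < day_end
               and recording_start + recording_duration_s > day_start)
    if overlap:
        for b in aggregate_hourly(list(events), recording_start, recording_duration_s):
            if day_start <= b.hour_start < day_end:
                counts[int((b.hour_start - day_start) // 3600)] = b.cough_count
        for h, mean in enumerate(activity.hourly_means):
            ts = recording_start + h * 3600.0
            if day_start <= ts < day_end:
                act[int((ts - day_start) // 3600)] = float(mean)
    meds = [
        {"timestamp": m.timestamp, "kind": m.kind, "note": m.note}
        for m in diary.medications_for_day(date)
    ]
    entries = [
        {"timestamp": e.timestamp, "text": e.text}
        for e in diary.entries_for_day(date)
    ]
    return DailyReport(date, counts, act, meds, entries, empty=not overlap)
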