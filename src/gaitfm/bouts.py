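"""Walking-bout segmentation for supervised and free-living recordings.

Free-living path: candidate activity is found with 2-s moving windows in
which the summed per-axis standard deviations of the tri-axial signal
exceed 0.1 g (:func:`detect_activity_windows`), short segments are
discarded (:func:`segment_bouts`), and each surviving segment must yield
at least five detected initial contacts before its first and last steps
are trimmed off (:func:`refine_bout`).  The tuning is deliberately
conservative — precision over recall — since a false bout contaminates
every downstream parameter while a missed bout only loses data.

Supervised path: annotation is authoritative; the trial interval (with
pauses removed) bypasses the energy detector entirely
(:func:`apply_trial_annotation`).

Free-living bouts are categorised by duration into 5–15 s, 15–30 s,
30–60 s and >60 s bands (half-open ``[low, high)``; exactly 60 s falls in
the >60 band).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import GaitEvents
from .preprocessing import UniformRecording

__all__ = [
    "TrialAnnotation",
    "BoutSegment",
    "WalkingBout",
    "BoutRejection",
    "detect_activity_windows",
    "segment_bouts",
    "refine_bout",
    "apply_trial_annotation",
    "categorize_duration",
    "BOUT_CATEGORIES",
]

BOUT_CATEGORIES = ("5-15s", "15-30s", "30-60s", ">60s")
_CATEGORY_EDGES = (5.0, 15.0, 30.0, 60.0)


@dataclass
class TrialAnnotation:
    """Therapist-marked trial bounds with optional manual adjustment."""

    trial_id: str
    marked_start: float
    marked_end: float
    pauses: list[tuple[float, float]] = field(default_factory=list)
    adjusted_start: float | None = None
    adjusted_end: float | None = None

    def __post_init__(self) -> None:
        if self.marked_start >= self.marked_end:
            raise ValueError("marked_start must precede marked_end")
        lo, hi = self.bounds
        prev_end = lo
        for s, e in sorted(self.pauses):
            if s < lo or e > hi:
                raise ValueError(f"pause ({s}, {e}) outside trial interval")
            if s < prev_end:
                raise ValueError("pauses overlap")
            if s >= e:
                raise ValueError("pause must have positive duration")
            prev_end = e

    @property
    def bounds(self) -> tuple[float, float]:
        start = self.marked_start if self.adjusted_start is None else self.adjusted_start
        end = self.marked_end if self.adjusted_end is None else self.adjusted_end
        return start, end

    @classmethod
    def from_dict(cls, d: dict) -> "TrialAnnotation":
        return cls(
            trial_id=d["trial_id"],
            marked_start=d["marked_start_s"],
            marked_end=d["marked_end_s"],
            pauses=[tuple(p) for p in d.get("pauses", [])],
            adjusted_start=d.get("adjusted_start_s"),
            adjusted_end=d.get("adjusted_end_s"),
        )


@dataclass
class BoutSegment:
    start: float
    end: float
    source: str = "free_living"  # or "supervised"
    trial_id: str | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment must have positive duration")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class WalkingBout:
    segment: BoutSegment
    events: GaitEvents  # trimmed
    n_steps: int
    duration: float
    category: str | None  # free-living only


@dataclass
class BoutRejection:
    segment: BoutSegment
    reason: str


def rolling_sd_sum(accel: np.ndarray, window_samples: int) -> np.ndarray:
    """Summed per-axis SD over a sliding window (stride 1 sample).

    Output has one value per window start; sample SD (ddof=1).
    """
    frame = pd.DataFrame(np.asarray(accel, dtype=float))
    sd = frame.rolling(window_samples).std(ddof=1).to_numpy()[window_samples - 1:]
    return sd.sum(axis=1)


def detect_activity_windows(
    rec: UniformRecording, window: float = 2.0, threshold: float = 0.1
) -> list[BoutSegment]:
    """Candidate movement segments from the summed-SD moving window.

    A window is active when the sum of the three axis SDs exceeds
    ``threshold`` (in g, on the filtered, offset-removed signal);
    overlapping/abutting active windows merge into maximal segments.
    """
    w = int(round(window * rec.sample_rate))
    if rec.n_samples < w:
        return []
    sums = rolling_sd_sum(rec.accel, w)
    active = sums > threshold
    segments: list[BoutSegment] = []
    i = 0
    n = active.size
    while i < n:
        if active[i]:
            j = i
            while j + 1 < n and active[j + 1]:
                j += 1
            start = rec.start_time + i / rec.sample_rate
            end = rec.start_time + (j + w - 1) / rec.sample_rate
            segments.append(BoutSegment(start, end, source="free_living"))
            i = j + 1
        else:
            i += 1
    return segments


def segment_bouts(
    segments: list[BoutSegment], min_duration: float = 5.0
) -> list[BoutSegment]:
    """Drop segments shorter than ``min_duration`` (order preserved)."""
    return [s for s in segments if s.duration > min_duration]


def categorize_duration(duration: float) -> str | None:
    """Free-living bout-length category, half-open bands, 60 s → '>60s'."""
    if duration < _CATEGORY_EDGES[0]:
        return None
    for lo, hi, name in zip(_CATEGORY_EDGES[:-1], _CATEGORY_EDGES[1:], BOUT_CATEGORIES):
        if lo <= duration < hi:
            return name
    return BOUT_CATEGORIES[-1]


def refine_bout(
    segment: BoutSegment, events: GaitEvents, min_ics: int = 5
) -> WalkingBout | BoutRejection:
    """Validate a candidate bout and trim its transition steps.

    Bouts with fewer than ``min_ics`` initial contacts are rejected.
    Otherwise the first and last detected steps are trimmed off (their
    transition characteristics are not steady-state walking) and the
    laterality sequence re-anchored.
    """
    if events.n_ics < min_ics:
        return BoutRejection(segment, f"only {events.n_ics} ICs (< {min_ics})")
    ic = events.ic_times[1:-1]
    sides = events.laterality[1:-1]
    lo, hi = ic[0], ic[-1]
    keep_fc = events.fc_times[(events.fc_times > lo) & (events.fc_times < hi)]
    paired = events.paired_fc[1:-1]
    trimmed = GaitEvents(
        ic_times=ic,
        fc_times=keep_fc,
        laterality=sides,
        cwt_scale=events.cwt_scale,
        paired_fc=paired,
        quality_flags=list(events.quality_flags) + ["first/last step trimmed"],
    )
    category = categorize_duration(segment.duration) if segment.source == "free_living" else None
    return WalkingBout(
        segment=segment,
        events=trimmed,
        n_steps=int(ic.size),
        duration=segment.duration,
        category=category,
    )


def apply_trial_annotation(
    rec: UniformRecording, ann: TrialAnnotation
) -> list[BoutSegment]:
    """Trial interval minus pauses, as ordered supervised segments."""
    start, end = ann.bounds
    t0 = rec.start_time
    t1 = rec.start_time + rec.duration
    if start < t0 - 1e-9 or end > t1 + 1e-9:
        raise ValueError("annotation outside recording span")
    pieces: list[BoutSegment] = []
    cursor = start
    for ps, pe in sorted(ann.pauses):
        if ps > cursor:
            pieces.append(BoutSegment(cursor, ps, "supervised", ann.trial_id))
        cursor = max(cursor, pe)
    if end > cursor:
        pieces.append(BoutSegment(cursor, end, "supervised", ann.trial_id))
    return pieces
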