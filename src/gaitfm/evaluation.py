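"""Detection quality against synthetic ground truth.

Event matching is greedy nearest-neighbour within a tolerance; bout
matching scores a detected bout as correct when most of it overlaps a true
walking interval.  These metrics drive the recovery tests and the
precision-over-recall tuning of the free-living path.
"""
from __future__ import annotations

import numpy as np

__all__ = ["match_events", "event_timing_errors", "bout_precision_recall", "interval_iou"]


def match_events(
    true_times: np.ndarray, detected_times: np.ndarray, tolerance: float = 0.1
) -> list[tuple[int, int]]:
    """One-to-one greedy matching of detected to true events.

    Pairs are formed in order of increasing |Δt|; each event participates
    in at most one pair; pairs beyond ``tolerance`` are discarded.
    """
    true_times = np.asarray(true_times, dtype=float)
    detected_times = np.asarray(detected_times, dtype=float)
    if true_times.size == 0 or detected_times.size == 0:
        return []
    cand = [
        (abs(t - d), i, j)
        for i, t in enumerate(true_times)
        for j, d in enumerate(detected_times)
        if abs(t - d) <= tolerance
    ]
    cand.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used_t or j in used_d:
            continue
        pairs.append((i, j))
        used_t.add(i)
        used_d.add(j)
    return pairs


def event_timing_errors(
    true_times: np.ndarray, detected_times: np.ndarray, tolerance: float = 0.1
) -> tuple[np.ndarray, float]:
    """(per-matched |Δt| array, fraction of true events matched)."""
    true_times = np.asarray(true_times, dtype=float)
    pairs = match_events(true_times, detected_times, tolerance)
    if true_times.size == 0:
        return np.empty(0), np.nan
    errs = np.array(
        [abs(true_times[i] - np.asarray(detected_times)[j]) for i, j in pairs]
    )
    return errs, len(pairs) / true_times.size


def interval_iou(a: tuple[float, float], b: tuple[float, float]) -> float:
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 0.0


def bout_precision_recall(
    true_intervals: list[tuple[float, float]],
    detected_intervals: list[tuple[float, float]],
    min_overlap_frac: float = 0.5,
) -> tuple[float, float]:
    """Precision/recall of detected bouts against true walking intervals.

    A detected bout is a true positive when at least ``min_overlap_frac``
    of its duration lies inside some true walking interval; a true
    interval counts as recalled when some detected bout covers at least
    half of it.
    """
    def overlap(x, y):
        return max(0.0, min(x[1], y[1]) - max(x[0], y[0]))

    tp = 0
    for d in detected_intervals:
        dur = d[1] - d[0]
        if dur <= 0:
            continue
        if any(overlap(d, t) >= min_overlap_frac * dur for t in true_intervals):
            tp += 1
    precision = tp / len(detected_intervals) if detected_intervals else np.nan
    recalled = 0
    for t in true_intervals:
        dur = t[1] - t[0]
        if any(overlap(d, t) >= 0.5 * dur for d in detected_intervals):
            recalled += 1
    recall = recalled / len(true_intervals) if true_intervals else np.nan
    return precision, recall
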