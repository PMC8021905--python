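"""Spatiotemporal gait parameters from detected events.

Per-step measures (:func:`compute_step_table`):

* temporal — step time ``ic[i+1]-ic[i]``, stride time ``ic[i+2]-ic[i]``,
  stance time ``fc_i - ic[i]`` where ``fc_i`` is the toe-off of foot *i*
  (the first FC after the next IC), swing = stride − stance, and double
  support = stance − step (the terminal-overlap convention under which
  stance ≈ 75% of the cycle implies double support ≈ 25%);
* spatial — the inverted-pendulum model: the vertical excursion ``h`` is
  the peak-to-trough of the twice-integrated, per-step linearly detrended
  vertical acceleration, and step length is ``2·sqrt(2 l h − h²)`` with
  pendulum length ``l`` from the sensor height (default 0.53 × body
  height).

Per-bout panel (:func:`summarize_bout`): means of the step series plus
variability (SD of each series, with coefficient-of-variation variants
exported alongside) and asymmetry (absolute left-right mean difference —
invariant to the arbitrary starting laterality label).  Stance% + swing%
is 100 by construction.

Per-subject aggregation (:func:`aggregate_subject`): step-count-weighted
means within each bout-length category (free-living) or trial type
(supervised).

:func:`step_count_validity` is the concurrent-validity check between
observer-reported and detected step counts: a two-way random,
absolute-agreement, single-measure intraclass correlation, ICC(2,1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .bouts import WalkingBout
from .events import GaitEvents
from .preprocessing import GRAVITY_MS2
from .synthetic import pendulum_step_length

__all__ = [
    "compute_step_table",
    "summarize_bout",
    "aggregate_subject",
    "step_count_validity",
    "PARAMETER_COLUMNS",
    "SubjectGaitSummary",
]

#: the canonical per-bout parameter panel
PARAMETER_COLUMNS = [
    "gait_velocity_mps",
    "cadence_spm",
    "stride_length_m",
    "stride_velocity_mps",
    "step_length_m",
    "step_velocity_mps",
    "stance_phase_pct",
    "swing_phase_pct",
    "double_support_phase_pct",
    "step_time_s",
    "stance_time_s",
    "swing_time_s",
    "double_support_time_s",
    "stride_time_variability",
    "step_length_variability",
    "step_time_variability",
    "step_velocity_variability",
    "stance_time_variability",
    "swing_time_variability",
    "double_support_variability",
    "stride_time_asymmetry",
    "step_time_asymmetry",
    "stance_time_asymmetry",
    "swing_time_asymmetry",
    "step_length_asymmetry",
]


def _per_step_excursion(
    vertical_accel: np.ndarray, sample_rate: float, i0: int, i1: int
) -> float:
    """Peak-to-trough of the doubly integrated, detrended vertical accel (m)."""
    seg = vertical_accel[i0 : i1 + 1] * GRAVITY_MS2
    if seg.size < 3:
        return np.nan
    dt = 1.0 / sample_rate
    vel = cumulative_trapezoid(seg - seg.mean(), dx=dt, initial=0.0)
    pos = cumulative_trapezoid(vel, dx=dt, initial=0.0)
    # endpoint-anchored linear detrend: the integration constants are a pure
    # line through the step's endpoints (an LS fit would bias the excursion
    # of a single oscillation period low)
    x = np.arange(pos.size)
    line = pos[0] + (pos[-1] - pos[0]) * x / (pos.size - 1)
    return float(np.ptp(pos - line))


def compute_step_table(
    events: GaitEvents,
    vertical_accel: np.ndarray,
    sample_rate: float,
    pendulum_length: float = 0.9,
    segment_start: float = 0.0,
) -> pd.DataFrame:
    """Per-step measures for one bout.

    ``vertical_accel`` is the segment's vertical channel (g, offset
    removed); event times are relative to ``segment_start``.  Steps whose
    excursion is implausible (``h >= l``) are flagged invalid and excluded
    from summaries.
    """
    ic = events.ic_times
    if ic.size < 3:
        raise ValueError("need at least 3 initial contacts")
    if pendulum_length <= 0:
        raise ValueError("pendulum_length must be positive")
    fc = events.fc_times
    sides = events.laterality
    n_steps = ic.size - 1
    rows = []
    for i in range(n_steps):
        step_time = ic[i + 1] - ic[i]
        stride_time = ic[i + 2] - ic[i] if i + 2 < ic.size else np.nan
        # toe-off of foot i: first FC after the next IC (within the stride)
        stance_time = np.nan
        if i + 2 < ic.size:
            cand = fc[(fc > ic[i + 1]) & (fc < ic[i + 2])]
            if cand.size:
                stance_time = cand[0] - ic[i]
        swing_time = stride_time - stance_time
        ds_time = stance_time - step_time
        i0 = int(round((ic[i] - segment_start) * sample_rate))
        i1 = int(round((ic[i + 1] - segment_start) * sample_rate))
        i0 = max(i0, 0)
        i1 = min(i1, len(vertical_accel) - 1)
        h = _per_step_excursion(vertical_accel, sample_rate, i0, i1)
        valid = bool(np.isfinite(h) and 0.0 < h < pendulum_length)
        step_length = pendulum_step_length(pendulum_length, h) if valid else np.nan
        rows.append(
            {
                "ic": ic[i],
                "next_ic": ic[i + 1],
                "side": sides[i],
                "step_time": step_time,
                "stride_time": stride_time,
                "stance_time": stance_time,
                "swing_time": swing_time,
                "double_support_time": ds_time,
                "excursion_h": h,
                "step_length": step_length,
                "step_velocity": step_length / step_time if valid else np.nan,
                "valid": valid,
            }
        )
    table = pd.DataFrame(rows)
    # stride length/velocity: two consecutive step lengths
    sl = table["step_length"].to_numpy()
    stride_len = np.full(len(table), np.nan)
    stride_len[:-1] = sl[:-1] + sl[1:]
    table["stride_length"] = stride_len
    table["stride_velocity"] = table["stride_length"] / table["stride_time"]
    return table


def _sd(x: pd.Series) -> float:
    x = x.dropna()
    return float(x.std(ddof=1)) if len(x) >= 2 else np.nan


def _asym(table: pd.DataFrame, col: str) -> float:
    """Absolute L-R difference of per-side means (starting-label invariant)."""
    by = table.groupby("side")[col].mean()
    if len(by) < 2:
        return np.nan
    return float(abs(by.get("L", np.nan) - by.get("R", np.nan)))


def summarize_bout(steps: pd.DataFrame) -> pd.Series:
    """The 25-parameter panel for one bout.

    Central values are means over valid steps; cadence is 60 / mean step
    time; variability is the SD of the per-step series (``*_cv`` variants
    appended); asymmetry is |mean(L) − mean(R)| in native units.
    """
    valid = steps[steps["valid"]] if "valid" in steps else steps
    if len(valid) < 2:
        raise ValueError("need at least 2 valid steps")
    mean_step_time = valid["step_time"].mean()
    stance_frac = (valid["stance_time"] / valid["stride_time"]).mean()
    ds_frac = (valid["double_support_time"] / valid["stride_time"]).mean()
    out = {
        "gait_velocity_mps": valid["step_velocity"].mean(),
        "cadence_spm": 60.0 / mean_step_time,
        "stride_length_m": valid["stride_length"].mean(),
        "stride_velocity_mps": valid["stride_velocity"].mean(),
        "step_length_m": valid["step_length"].mean(),
        "step_velocity_mps": valid["step_velocity"].mean(),
        "stance_phase_pct": 100.0 * stance_frac,
        "swing_phase_pct": 100.0 * (1.0 - stance_frac),
        "double_support_phase_pct": 100.0 * ds_frac,
        "step_time_s": mean_step_time,
        "stance_time_s": valid["stance_time"].mean(),
        "swing_time_s": valid["swing_time"].mean(),
        "double_support_time_s": valid["double_support_time"].mean(),
        "stride_time_variability": _sd(valid["stride_time"]),
        "step_length_variability": _sd(valid["step_length"]),
        "step_time_variability": _sd(valid["step_time"]),
        "step_velocity_variability": _sd(valid["step_velocity"]),
        "stance_time_variability": _sd(valid["stance_time"]),
        "swing_time_variability": _sd(valid["swing_time"]),
        "double_support_variability": _sd(valid["double_support_time"]),
        "stride_time_asymmetry": _asym(valid, "stride_time"),
        "step_time_asymmetry": _asym(valid, "step_time"),
        "stance_time_asymmetry": _asym(valid, "stance_time"),
        "swing_time_asymmetry": _asym(valid, "swing_time"),
        "step_length_asymmetry": _asym(valid, "step_length"),
    }
    # coefficient-of-variation variants of the variability entries
    for name, col in [
        ("stride_time", "stride_time"),
        ("step_length", "step_length"),
        ("step_time", "step_time"),
        ("step_velocity", "step_velocity"),
        ("stance_time", "stance_time"),
        ("swing_time", "swing_time"),
        ("double_support", "double_support_time"),
    ]:
        mean = valid[col].mean()
        out[f"{name}_variability_cv"] = (
            100.0 * _sd(valid[col]) / abs(mean) if mean else np.nan
        )
    out["n_steps"] = float(len(valid))
    return pd.Series(out)


@dataclass
class SubjectGaitSummary:
    """Step-weighted per-condition aggregate for one subject/visit."""

    subject_id: str
    visit: str
    table: pd.DataFrame  # indexed by condition/category

    def condition(self, name: str) -> pd.Series:
        return self.table.loc[name]


def aggregate_subject(
    bouts: list[tuple[WalkingBout, pd.Series]],
    mode: str = "free_living",
    subject_id: str = "S001",
    visit: str = "admission",
) -> SubjectGaitSummary:
    """Step-count-weighted mean of each parameter per category.

    Free-living bouts aggregate within their duration category; supervised
    bouts aggregate per trial id.  Empty categories are absent (never
    zero-filled).
    """
    groups: dict[str, list[tuple[pd.Series, float]]] = {}
    for bout, params in bouts:
        key = (
            bout.category if mode == "free_living" else (bout.segment.trial_id or "trial")
        )
        if key is None:
            continue
        groups.setdefault(key, []).append((params, float(bout.n_steps)))
    rows = {}
    for key, members in groups.items():
        mat = pd.concat([p for p, _ in members], axis=1)
        weights = np.array([w for _, w in members])
        agg = (mat * weights).sum(axis=1) / weights.sum()
        agg["n_bouts"] = float(len(members))
        agg["total_steps"] = float(weights.sum())
        rows[key] = agg
    table = pd.DataFrame(rows).T
    return SubjectGaitSummary(subject_id=subject_id, visit=visit, table=table)


def step_count_validity(reported: np.ndarray, detected: np.ndarray) -> float:
    """ICC(2,1): two-way random, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares with trials as rows and
    the two counting methods (observer, detector) as raters.
    """
    x = np.column_stack([np.asarray(reported, float), np.asarray(detected, float)])
    n, k = x.shape
    if n < 2:
        raise ValueError("need at least 2 trials")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("zero variance in both raters; ICC undefined")
    return float((msr - mse) / denom)
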