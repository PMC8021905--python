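"""Synthetic lumbar-accelerometer recordings and clinical cohorts.

Every downstream stage of the pipeline is validated against data with
*known* ground truth, generated here:

* :func:`simulate_gait_recording` builds a tri-axial acceleration signal
  from an analytic waveform model (see below) together with the exact
  initial/final-contact times, lateralities, step lengths and walking-bout
  intervals used to construct it.
* :func:`perturb_sampling` degrades the time base (clock jitter, dropped
  samples) the way real loggers do.
* :func:`simulate_cohort` draws a paired admission/discharge clinical
  outcomes table with prescribed change distributions and, optionally, a
  known sparse linear model linking predictor changes to the change of a
  response outcome.

Waveform model
--------------
The vertical channel within a walking bout is built analytically so the
ground truth is exact (no ODE solver):

* a per-step sinusoidal oscillation ``-A sin(2π(t - t_ic)/T)`` whose double
  integral has peak-to-trough excursion ``h`` (``A = h (2π/T)² / 2``) — the
  vertical centre-of-mass movement of the inverted-pendulum model;
* a 30 ms raised-cosine impact transient at each initial contact;
* an odd (Gaussian-derivative, σ = 20 ms) toe-off transient at each final
  contact — the signature the final-contact detector keys on;
* +1 g gravity and white sensor noise; the result is clipped to the
  device's dynamic range.

Rest segments are gravity plus noise; ``random_movement`` segments are
low-pass-filtered noise bursts that exceed the walking-bout energy
threshold but contain no locomotor periodicity (false-positive bait for
the bout detector).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter

from .preprocessing import GRAVITY_MS2, RawRecording
from .reference import CLINICAL_OUTCOMES

__all__ = [
    "GaitProfile",
    "ActivitySegment",
    "ActivitySchedule",
    "GroundTruth",
    "OutcomeSpec",
    "LinearChangeModel",
    "CohortSpec",
    "simulate_gait_recording",
    "perturb_sampling",
    "simulate_cohort",
    "default_cohort_spec",
    "pendulum_step_length",
]


def pendulum_step_length(pendulum_length: float, excursion: float) -> float:
    """Inverted-pendulum step length: ``2 sqrt(2 l h - h²)``."""
    if not 0.0 < excursion < pendulum_length:
        raise ValueError("need 0 < h < l")
    return 2.0 * np.sqrt(2.0 * pendulum_length * excursion - excursion**2)


@dataclass
class GaitProfile:
    """Ground-truth gait of one synthetic walker.

    ``vertical_excursion_h`` may be a scalar or a (left, right) pair to
    induce spatial asymmetry; ``step_time_asym`` is the systematic
    left-minus-right step-time offset.  ``stance_fraction`` is the stance
    phase as a fraction of the gait cycle (healthy ≈ 0.6; the PD cohort
    this package models shows ≈ 0.75).
    """

    step_time_mean: float = 0.6
    step_time_sd: float = 0.0
    step_time_asym: float = 0.0
    vertical_excursion_h: float | tuple[float, float] = 0.02
    pendulum_length_l: float = 0.9
    impact_amplitude: float = 0.15
    toe_off_amplitude: float = 0.5
    stance_fraction: float = 0.6
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.step_time_asym < 0 or self.step_time_mean <= 2 * self.step_time_asym:
            raise ValueError("need step_time_mean > 2*step_time_asym >= 0")
        if self.step_time_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        for h in self.excursions:
            if not 0.0 < h < self.pendulum_length_l:
                raise ValueError("need 0 < vertical_excursion_h < pendulum_length_l")
        if not 0.5 < self.stance_fraction < 0.9:
            raise ValueError("stance_fraction must lie in (0.5, 0.9)")

    @property
    def excursions(self) -> tuple[float, float]:
        """Per-side (left, right) vertical excursion in metres."""
        h = self.vertical_excursion_h
        return (h, h) if np.isscalar(h) else (float(h[0]), float(h[1]))

    def side_step_time(self, side: str) -> float:
        return self.step_time_mean + (0.5 if side == "L" else -0.5) * self.step_time_asym


@dataclass
class ActivitySegment:
    kind: str  # "rest" | "walk" | "random_movement"
    duration: float
    profile: GaitProfile | None = None
    amplitude: float = 0.25  # random_movement burst amplitude, g

    def __post_init__(self) -> None:
        if self.kind not in ("rest", "walk", "random_movement"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("segment durations must be positive")


@dataclass
class ActivitySchedule:
    segments: list[ActivitySegment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule must be non-empty")

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)

    @classmethod
    def single_walk(cls, duration: float, profile: GaitProfile | None = None,
                    pad: float = 0.0) -> "ActivitySchedule":
        segs = []
        if pad > 0:
            segs.append(ActivitySegment("rest", pad))
        segs.append(ActivitySegment("walk", duration, profile))
        if pad > 0:
            segs.append(ActivitySegment("rest", pad))
        return cls(segs)


@dataclass
class GroundTruth:
    """Constructed events: the oracle for every detection stage."""

    ic_times: np.ndarray
    fc_times: np.ndarray
    laterality: list[str]
    true_step_lengths: np.ndarray
    true_bout_intervals: list[tuple[float, float]]
    true_step_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    stance_fraction: float = 0.6

    def __post_init__(self) -> None:
        self.ic_times = np.asarray(self.ic_times, dtype=float)
        self.fc_times = np.asarray(self.fc_times, dtype=float)
        self.true_step_lengths = np.asarray(self.true_step_lengths, dtype=float)
        self.true_step_times = np.asarray(self.true_step_times, dtype=float)

    def to_dict(self) -> dict:
        return {
            "ic_s": self.ic_times.tolist(),
            "fc_s": self.fc_times.tolist(),
            "laterality": list(self.laterality),
            "step_lengths_m": self.true_step_lengths.tolist(),
            "bout_intervals_s": [list(b) for b in self.true_bout_intervals],
            "step_times_s": self.true_step_times.tolist(),
            "stance_fraction": self.stance_fraction,
        }


# transient shapes -----------------------------------------------------------

_IMPACT_HALF_WIDTH = 0.015  # s: 30 ms raised cosine
_TOE_OFF_SIGMA = 0.02  # s


def _add_impact(a: np.ndarray, t: np.ndarray, t0: float, amp: float) -> None:
    m = np.abs(t - t0) <= _IMPACT_HALF_WIDTH
    a[m] += amp * 0.5 * (1.0 + np.cos(np.pi * (t[m] - t0) / _IMPACT_HALF_WIDTH))


def _add_toe_off(a: np.ndarray, t: np.ndarray, t0: float, amp: float) -> None:
    m = np.abs(t - t0) <= 5 * _TOE_OFF_SIGMA
    u = (t[m] - t0) / _TOE_OFF_SIGMA
    a[m] += amp * u * np.exp(-0.5 * u * u)


def _walk_events(
    profile: GaitProfile, start: float, end: float, rng: np.random.Generator,
    first_side: str = "L",
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """IC times, sides and realised step times for one bout."""
    ics = [start]
    sides = [first_side]
    steps: list[float] = []
    t = start
    min_step = 0.25 * profile.step_time_mean
    while True:
        side = sides[-1]
        T = profile.side_step_time(side) + rng.normal(0.0, profile.step_time_sd)
        T = max(T, min_step)
        if t + T > end + 1e-9:
            break
        t += T
        steps.append(T)
        ics.append(t)
        sides.append("R" if side == "L" else "L")
    return np.asarray(ics), sides, np.asarray(steps)


def simulate_gait_recording(
    profile: GaitProfile,
    schedule: ActivitySchedule,
    sample_rate: float = 100.0,
    seed: int | np.random.Generator = 0,
    rotation: np.ndarray | None = None,
) -> tuple[RawRecording, GroundTruth]:
    """Generate a recording plus exact ground truth.

    ``profile`` is the default gait; walk segments carrying their own
    profile override it.  ``rotation`` (3×3) re-expresses the channels in a
    rotated sensor frame, to exercise orientation detection downstream.
    """
    if sample_rate < 50:
        raise ValueError("sample_rate must be at least 50 Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    total = schedule.total_duration
    t = np.arange(0.0, total, 1.0 / sample_rate)
    n = t.size
    vert = np.zeros(n)  # oscillation in g, gravity added later
    ml = np.zeros(n)
    ap = np.zeros(n)

    all_ic: list[float] = []
    all_fc: list[float] = []
    all_sides: list[str] = []
    all_lengths: list[float] = []
    all_steps: list[float] = []
    bout_intervals: list[tuple[float, float]] = []

    seg_start = 0.0
    for seg in schedule.segments:
        seg_end = seg_start + seg.duration
        if seg.kind == "walk":
            prof = seg.profile or profile
            if seg.duration < prof.step_time_mean:
                warnings.warn(
                    f"walk segment of {seg.duration:.2f} s is shorter than one "
                    "step; no events generated",
                    stacklevel=2,
                )
                seg_start = seg_end
                continue
            ics, sides, steps = _walk_events(prof, seg_start, seg_end, rng)
            hL, hR = prof.excursions
            for i, T in enumerate(steps):
                t0 = ics[i]
                m = (t >= t0) & (t < t0 + T)
                w = 2.0 * np.pi / T
                h = hL if sides[i] == "L" else hR
                A = h * w * w / 2.0 / GRAVITY_MS2  # g
                phase = w * (t[m] - t0)
                vert[m] += -A * np.sin(phase)
                ap[m] += 0.4 * A * np.cos(phase)
                all_lengths.append(pendulum_step_length(prof.pendulum_length_l, h))
            # mediolateral sway at stride frequency
            if steps.size:
                stride = 2.0 * prof.step_time_mean
                m = (t >= seg_start) & (t < ics[-1])
                ml[m] += 0.05 * np.sin(2.0 * np.pi * (t[m] - seg_start) / stride)
            for t0 in ics:
                _add_impact(vert, t, t0, prof.impact_amplitude)
            fcs = [
                ics[i] + prof.stance_fraction * (ics[i + 2] - ics[i])
                for i in range(len(ics) - 2)
            ]
            for tf in fcs:
                _add_toe_off(vert, t, tf, prof.toe_off_amplitude)
            if ics.size:
                all_ic.extend(ics)
                all_sides.extend(sides)
                all_fc.extend(fcs)
                all_steps.extend(steps)
                bout_intervals.append((seg_start, seg_end))
        elif seg.kind == "random_movement":
            m = (t >= seg_start) & (t < seg_end)
            b, a = butter(2, 3.0 / (sample_rate / 2.0), btype="low")
            for chan in (vert, ml, ap):
                burst = rng.normal(0.0, 1.0, int(m.sum()))
                burst = lfilter(b, a, burst)
                sd = burst.std()
                if sd > 0:
                    chan[m] += seg.amplitude * burst / sd
        seg_start = seg_end

    noise = rng.normal(0.0, profile.noise_sd, (n, 3)) if profile.noise_sd else 0.0
    accel = np.column_stack([vert + 1.0, ml, ap])
    accel = accel + noise
    if rotation is not None:
        accel = accel @ np.asarray(rotation, dtype=float).T
    accel = np.clip(accel, -8.0, 8.0)

    truth = GroundTruth(
        ic_times=np.asarray(all_ic),
        fc_times=np.asarray(all_fc),
        laterality=all_sides,
        true_step_lengths=np.asarray(all_lengths),
        true_bout_intervals=bout_intervals,
        true_step_times=np.asarray(all_steps),
        stance_fraction=profile.stance_fraction,
    )
    rec = RawRecording(timestamps=t, accel=accel, nominal_rate=sample_rate)
    return rec, truth


def perturb_sampling(
    rec: RawRecording,
    jitter_sd: float = 0.0,
    drop_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> RawRecording:
    """Jitter timestamps and drop samples, keeping values at kept samples.

    Jitter that would break monotonicity is redrawn at the offending
    samples (never an error).  The first and last samples are always kept
    so the recorded span is preserved.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    if not 0.0 <= drop_rate < 0.5:
        raise ValueError("drop_rate must lie in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    ts = rec.timestamps.copy()
    if jitter_sd > 0:
        jit = rng.normal(0.0, jitter_sd, ts.size)
        jit[0] = jit[-1] = 0.0
        for _ in range(100):
            cand = ts + jit
            bad = np.nonzero(np.diff(cand) <= 0)[0]
            if bad.size == 0:
                break
            idx = np.unique(np.concatenate([bad, bad + 1]))
            idx = idx[(idx > 0) & (idx < ts.size - 1)]
            jit[idx] = rng.normal(0.0, jitter_sd, idx.size)
        else:  # pathological jitter: shrink it until monotone
            cand = ts + np.clip(jit, -0.4 / rec.nominal_rate, 0.4 / rec.nominal_rate)
        ts = cand
    keep = np.ones(ts.size, dtype=bool)
    if drop_rate > 0:
        keep = rng.random(ts.size) >= drop_rate
        keep[0] = keep[-1] = True
    return RawRecording(
        timestamps=ts[keep],
        accel=rec.accel[keep],
        nominal_rate=rec.nominal_rate,
        dynamic_range=rec.dynamic_range,
    )


# cohort simulation ----------------------------------------------------------


@dataclass
class OutcomeSpec:
    """Admission and change distribution of one clinical outcome."""

    name: str
    admission_mean: float
    admission_sd: float
    change_mean: float
    change_sd: float

    def __post_init__(self) -> None:
        if self.admission_sd <= 0 or self.change_sd <= 0:
            raise ValueError("SDs must be positive")


@dataclass
class LinearChangeModel:
    """Sparse linear model: response change = Σ βⱼ · predictor-change + ε."""

    response: str
    predictors: list[str]
    coefficients: np.ndarray
    noise_sd: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.size != len(self.predictors):
            raise ValueError("coefficient vector length must match predictors")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class CohortSpec:
    outcomes: list[OutcomeSpec]
    n_subjects: int = 24
    change_model: LinearChangeModel | None = None
    missingness: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must lie in [0, 1)")
        names = [o.name for o in self.outcomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate outcome names")
        if self.change_model is not None:
            missing = set(self.change_model.predictors + [self.change_model.response]) - set(names)
            if missing:
                raise ValueError(f"change model references unknown outcomes {missing}")


def simulate_cohort(spec: CohortSpec, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw a paired admission/discharge table.

    Returns a long-format frame with columns
    ``subject_id, outcome, admission, discharge``.  When ``spec.change_model``
    is set, the response outcome's change is the prescribed linear
    combination of the (noise-free) predictor changes plus Gaussian noise;
    otherwise every change is drawn from its own outcome spec.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_subjects

    adm = {o.name: rng.normal(o.admission_mean, o.admission_sd, n) for o in spec.outcomes}
    chg = {o.name: rng.normal(o.change_mean, o.change_sd, n) for o in spec.outcomes}
    if spec.change_model is not None:
        m = spec.change_model
        x = np.column_stack([chg[p] for p in m.predictors])
        eps = rng.normal(0.0, m.noise_sd, n) if m.noise_sd > 0 else 0.0
        chg[m.response] = m.intercept + x @ m.coefficients + eps

    rows = []
    for o in spec.outcomes:
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"S{i + 1:03d}",
                    "outcome": o.name,
                    "admission": adm[o.name][i],
                    "discharge": adm[o.name][i] + chg[o.name][i],
                }
            )
    table = pd.DataFrame(rows)

    if spec.missingness > 0:
        hit = rng.random(len(table)) < spec.missingness
        which = rng.random(len(table)) < 0.5
        table.loc[hit & which, "admission"] = np.nan
        table.loc[hit & ~which, "discharge"] = np.nan
    return table


def default_cohort_spec(
    n_subjects: int = 24,
    missingness: float = 0.0,
    with_change_model: bool = False,
) -> CohortSpec:
    """Cohort emulating the published clinical table.

    With ``with_change_model``, the TUG change is generated from the TUG
    Cognitive change with the published regression coefficient (B = 0.42)
    and a noise SD chosen to give R² ≈ 0.75, matching the published
    single-predictor model.
    """
    outcomes = [
        OutcomeSpec(s.name, s.admission_mean, s.admission_sd, s.change_mean, s.change_sd)
        for s in CLINICAL_OUTCOMES.values()
    ]
    model = None
    if with_change_model:
        beta, r2 = 0.42, 0.75
        pred_sd = CLINICAL_OUTCOMES["TUG Cognitive"].change_sd
        explained = (beta * pred_sd) ** 2
        noise_sd = float(np.sqrt(explained * (1.0 / r2 - 1.0)))
        model = LinearChangeModel(
            response="TUG Normal",
            predictors=["TUG Cognitive"],
            coefficients=np.array([beta]),
            noise_sd=noise_sd,
            intercept=CLINICAL_OUTCOMES["TUG Normal"].change_mean
            - beta * CLINICAL_OUTCOMES["TUG Cognitive"].change_mean,
        )
    return CohortSpec(
        outcomes=outcomes,
        n_subjects=n_subjects,
        change_model=model,
        missingness=missingness,
    )
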