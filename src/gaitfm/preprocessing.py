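"""Raw-to-analysis signal conditioning for lumbar accelerometry.

A recording from a trunk-worn tri-axial accelerometer (nominally 100 Hz,
±8 g, worn at L5) is turned into a uniformly sampled, offset-free,
low-pass-filtered signal with a resolved vertical axis:

1. :func:`resample_uniform` — linear interpolation onto a uniform grid,
   absorbing sample-rate jitter and dropped samples;
2. :func:`remove_offset` — per-axis mean subtraction (the pre-subtraction
   means are kept: the gravity component identifies the vertical axis);
3. :func:`lowpass_filter` — zero-phase second-order Butterworth, 17 Hz;
4. :func:`orient_vertical` — pick the axis whose mean is closest to ±1 g.

All values are in g throughout; conversion to m/s² happens only where
displacement is integrated (see :mod:`gaitfm.parameters`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "RawRecording",
    "UniformRecording",
    "resample_uniform",
    "remove_offset",
    "lowpass_filter",
    "orient_vertical",
    "preprocess",
]

#: exact gravity constant used for g ↔ m/s² conversion package-wide
GRAVITY_MS2 = 9.81


@dataclass
class RawRecording:
    """Timestamped tri-axial acceleration, possibly irregularly sampled.

    Parameters
    ----------
    timestamps
        Sample times in seconds, strictly increasing.
    accel
        Array of shape ``(n, 3)`` in g, channel order
        (vertical, mediolateral, anteroposterior) for the synthetic
        generator; real devices may be arbitrarily oriented.
    nominal_rate
        The programmed sample rate in Hz.
    dynamic_range
        Clipping range of the sensor in g.
    """

    timestamps: np.ndarray
    accel: np.ndarray
    nominal_rate: float = 100.0
    dynamic_range: float = 8.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if self.timestamps.ndim != 1 or self.timestamps.size < 2:
            raise ValueError("recording needs at least 2 samples")
        if self.accel.shape != (self.timestamps.size, 3):
            raise ValueError("accel must have shape (n_samples, 3)")
        dt = np.diff(self.timestamps)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            raise ValueError(
                f"timestamps not strictly increasing at index {bad[0] + 1}"
            )
        if np.any(np.abs(self.accel) > self.dynamic_range + 1e-9):
            raise ValueError("acceleration exceeds dynamic range")

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class UniformRecording:
    """Uniformly resampled tri-axial acceleration.

    ``axis_means`` holds the per-axis means before offset removal; the
    gravity direction is read from them.  ``vertical_axis``/``vertical_sign``
    are set by :func:`orient_vertical` and must be resolved before gait
    event detection.
    """

    start_time: float
    sample_rate: float
    accel: np.ndarray
    axis_means: np.ndarray | None = None
    vertical_axis: int | None = None
    vertical_sign: float = 1.0
    filtered: bool = False
    offset_removed: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.accel.shape[0]

    @property
    def duration(self) -> float:
        return (self.n_samples - 1) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate

    def vertical(self) -> np.ndarray:
        """Signed vertical channel (positive up)."""
        if self.vertical_axis is None:
            raise ValueError("vertical axis not resolved; run orient_vertical")
        return self.vertical_sign * self.accel[:, self.vertical_axis]

    def index_at(self, t: float) -> int:
        return int(round((t - self.start_time) * self.sample_rate))


def resample_uniform(rec: RawRecording, target_rate: float = 100.0) -> UniformRecording:
    """Resample onto a uniform grid by linear interpolation.

    The grid is anchored at the first timestamp and never extends past the
    last one (no extrapolation).
    """
    span = rec.timestamps[-1] - rec.timestamps[0]
    if span < 2.0 / target_rate:
        raise ValueError("recording too short to resample at this rate")
    n = int(np.floor(span * target_rate)) + 1
    grid = rec.timestamps[0] + np.arange(n) / target_rate
    out = np.column_stack(
        [np.interp(grid, rec.timestamps, rec.accel[:, k]) for k in range(3)]
    )
    return UniformRecording(
        start_time=float(rec.timestamps[0]),
        sample_rate=float(target_rate),
        accel=out,
    )


def remove_offset(rec: UniformRecording) -> UniformRecording:
    """Subtract the per-axis mean over the whole recording.

    The pre-subtraction means are stored on the result so the gravity axis
    can still be identified afterwards.
    """
    means = rec.accel.mean(axis=0)
    return replace(
        rec,
        accel=rec.accel - means,
        axis_means=means,
        offset_removed=True,
    )


def lowpass_filter(
    rec: UniformRecording, cutoff: float = 17.0, order: int = 2
) -> UniformRecording:
    """Zero-phase (forward-backward) Butterworth low-pass per axis.

    Applied twice (filtfilt), the magnitude response at the cutoff is
    |H|² = 0.5; gait content (< 5 Hz) passes essentially untouched while
    machine noise is removed.
    """
    nyq = rec.sample_rate / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist {nyq} Hz")
    b, a = butter(order, cutoff / nyq, btype="low")
    out = filtfilt(b, a, rec.accel, axis=0)
    return replace(rec, accel=out, filtered=True)


def orient_vertical(rec: UniformRecording) -> UniformRecording:
    """Identify the gravity axis from the pre-subtraction means.

    The vertical axis is the one whose |mean| is closest to 1 g; the sign is
    chosen so vertical acceleration is positive upward.
    """
    if rec.axis_means is None:
        raise ValueError("axis means unavailable; run remove_offset first")
    means = np.asarray(rec.axis_means, dtype=float)
    dist = np.abs(np.abs(means) - 1.0)
    axis = int(np.argmin(dist))
    if not (0.5 <= abs(means[axis]) <= 1.5):
        raise ValueError("cannot identify gravity axis")
    return replace(
        rec,
        vertical_axis=axis,
        vertical_sign=1.0 if means[axis] >= 0 else -1.0,
    )


def preprocess(
    rec: RawRecording,
    target_rate: float = 100.0,
    cutoff: float = 17.0,
    order: int = 2,
) -> UniformRecording:
    """Full conditioning chain: resample → de-offset → filter → orient."""
    out = resample_uniform(rec, target_rate)
    out = remove_offset(out)
    out = lowpass_filter(out, cutoff=cutoff, order=order)
    return orient_vertical(out)
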