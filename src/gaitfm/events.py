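"""Gait event detection from vertical lumbar acceleration.

Initial contacts (IC, heel strike) and final contacts (FC, toe off) are
detected with the continuous-wavelet-transform differentiation approach
standard for single lumbar sensors:

1. the mean-centred vertical acceleration is integrated (cumulative
   trapezoid);
2. the integral is smoothed/differentiated with a ``gaus2``
   (second-derivative-of-Gaussian) CWT at a scale matched to the walker's
   dominant step frequency — ICs are the local minima of the coefficients;
3. the integral is differentiated twice more at a finer scale
   (``scale / fc_scale_divisor``) — FCs are the local maxima.  The finer
   scale is needed because the toe-off signature is a sharp transient,
   while the centre-of-mass oscillation that anchors the ICs lives at the
   step frequency; at the step-frequency scale the second differentiation
   of a near-sinusoidal signal has extrema at fixed phases and carries no
   final-contact information.

The CWT is computed by convolving with the ``gaus2`` wavelet sampled from
PyWavelets onto a symmetric grid, which is exactly zero-phase (the
event times must not be lag-shifted).  Extrema are refined to sub-sample
precision by parabolic interpolation.

The scale is *estimated per segment* from the spectral peak in the
locomotor band (0.5–4 Hz), adapting to patient-specific cadence.
Laterality cannot be recovered from a single vertical channel, so labels
alternate starting from an arbitrary "L"; all downstream asymmetry
measures are invariant to the starting label.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks, welch

__all__ = [
    "GaitEvents",
    "cwt_gaus2",
    "estimate_cwt_scale",
    "detect_initial_contacts",
    "detect_final_contacts",
    "assemble_events",
    "detect_events",
    "GAUS2_CENTER_FREQUENCY",
]

GAUS2_CENTER_FREQUENCY = pywt.central_frequency("gaus2")  # 0.3

# frozen detector settings (design-time choices, see docs/methods.md)
DEFAULT_REFRACTORY_S = 0.25
DEFAULT_FC_SCALE_DIVISOR = 4.0
IC_HEIGHT_FRACTION = 0.3
FC_HEIGHT_FRACTION = 0.4
LOCOMOTOR_BAND_HZ = (0.5, 4.0)
PEAK_TO_MEDIAN_MIN = 8.0  # spectral peak must stand this far above the band floor


@dataclass
class GaitEvents:
    """Detected and paired gait events for one segment.

    ``laterality`` alternates L/R aligned to ICs (arbitrary start);
    ``paired_fc`` holds, per IC, the FC that ends that foot's stance (the
    first FC after the *next* IC), or NaN when unpairable.
    ``quality_flags`` records degraded events (unpaired ICs, dropped FCs).
    """

    ic_times: np.ndarray
    fc_times: np.ndarray
    laterality: list[str]
    cwt_scale: float
    paired_fc: np.ndarray = field(default_factory=lambda: np.empty(0))
    quality_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ic_times = np.asarray(self.ic_times, dtype=float)
        self.fc_times = np.asarray(self.fc_times, dtype=float)
        if self.paired_fc.size == 0 and self.ic_times.size:
            self.paired_fc = np.full(self.ic_times.size, np.nan)

    @property
    def n_ics(self) -> int:
        return int(self.ic_times.size)

    def to_dict(self) -> dict:
        return {
            "ic_s": self.ic_times.tolist(),
            "fc_s": self.fc_times.tolist(),
            "laterality": list(self.laterality),
            "scale": self.cwt_scale,
            "flags": list(self.quality_flags),
        }


def _gaus2_kernel(scale: float, precision: int = 8) -> np.ndarray:
    """The gaus2 wavelet sampled symmetrically at the given scale.

    Sampling the wavelet from PyWavelets onto an odd-length symmetric grid
    and convolving gives an exactly zero-phase transform (pywt.cwt's
    diff-of-integral implementation carries a sub-sample lag).
    """
    wav = pywt.ContinuousWavelet("gaus2")
    psi, x = wav.wavefun(10)
    half = int(np.ceil(scale * max(abs(x[0]), abs(x[-1]))))
    grid = np.arange(-half, half + 1) / scale
    kern = np.interp(grid, x, psi, left=0.0, right=0.0)
    # negated so the coefficient sign matches pywt.cwt's convention
    return -kern / np.sqrt(scale)


def cwt_gaus2(signal: np.ndarray, scale: float) -> np.ndarray:
    """Zero-phase gaus2 CWT coefficients at a single scale."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    kern = _gaus2_kernel(scale)
    return np.convolve(np.asarray(signal, dtype=float), kern[::-1], mode="same")


def estimate_cwt_scale(
    vertical_accel: np.ndarray,
    sample_rate: float,
    band: tuple[float, float] = LOCOMOTOR_BAND_HZ,
    scale_bounds: tuple[float, float] = (5.0, 80.0),
) -> float:
    """Scale matched to the dominant step frequency.

    The spectral peak of the vertical channel within the locomotor band
    gives the step frequency ``f*``; the returned scale maps the gaus2
    centre frequency onto it: ``scale = sample_rate · f_c / f*``.  Raises
    when no peak stands clear of the in-band noise floor (non-locomotor
    signal).
    """
    x = np.asarray(vertical_accel, dtype=float)
    if x.size < 4 * sample_rate:
        raise ValueError("segment shorter than 4 s; cannot estimate scale")
    x = x - x.mean()
    # peak-vs-floor decision on a Welch-averaged spectrum (stable floor) ...
    nperseg = min(x.size, 256)
    f_w, p_w = welch(x, fs=sample_rate, nperseg=nperseg)
    mw = (f_w >= band[0]) & (f_w <= band[1])
    floor = np.median(p_w[mw])
    if floor <= 0 or p_w[mw].max() < PEAK_TO_MEDIAN_MIN * floor:
        raise ValueError("no locomotor band peak")
    # ... peak location at full spectral resolution
    spec = np.abs(np.fft.rfft(x * np.hanning(x.size))) ** 2
    freqs = np.fft.rfftfreq(x.size, 1.0 / sample_rate)
    m = (freqs >= band[0]) & (freqs <= band[1])
    f_star = float(freqs[m][np.argmax(spec[m])])
    scale = sample_rate * GAUS2_CENTER_FREQUENCY / f_star
    return float(np.clip(scale, *scale_bounds))


def _refine_extrema(y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Parabolic sub-sample refinement of extremum indices."""
    out = np.asarray(idx, dtype=float).copy()
    for k, i in enumerate(idx):
        if 0 < i < y.size - 1:
            denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
            if denom != 0:
                out[k] = i + 0.5 * (y[i - 1] - y[i + 1]) / denom
    return out


def _extrema_times(
    coeffs: np.ndarray,
    sample_rate: float,
    refractory: float,
    height_fraction: float,
    minima: bool,
) -> np.ndarray:
    y = -coeffs if minima else coeffs
    top = y.max()
    if not np.isfinite(top) or top <= 0:
        return np.empty(0)
    peaks, _ = find_peaks(
        y, distance=max(int(refractory * sample_rate), 1), height=height_fraction * top
    )
    if peaks.size < 2:
        return np.empty(0)
    return _refine_extrema(y, peaks) / sample_rate


def detect_initial_contacts(
    vertical_accel: np.ndarray,
    sample_rate: float,
    scale: float,
    refractory: float = DEFAULT_REFRACTORY_S,
    polarity: int = 1,
) -> np.ndarray:
    """IC times (s, relative to segment start) from the vertical channel.

    ICs are local minima of the gaus2 CWT of the integrated, mean-centred
    vertical acceleration (``polarity=-1`` flips the extremum convention
    for sensors mounted upside down or time-reversed analyses).
    Returns an empty array when fewer than two candidate minima exist.
    """
    x = np.asarray(vertical_accel, dtype=float)
    x = x - x.mean()
    if not np.any(x):
        return np.empty(0)
    z = cumulative_trapezoid(x, dx=1.0 / sample_rate, initial=0.0)
    c1 = polarity * cwt_gaus2(z, scale)
    return _extrema_times(c1, sample_rate, refractory, IC_HEIGHT_FRACTION, minima=True)


def detect_final_contacts(
    vertical_accel: np.ndarray,
    sample_rate: float,
    scale: float,
    refractory: float = DEFAULT_REFRACTORY_S,
    fc_scale_divisor: float = DEFAULT_FC_SCALE_DIVISOR,
    polarity: int = -1,
) -> np.ndarray:
    """FC times from a second, finer-scale CWT differentiation.

    The integrated signal is differentiated twice with gaus2 at
    ``scale / fc_scale_divisor``; FCs are the local maxima of
    ``polarity · coefficients``.  Peak-polarity conventions differ across
    CWT implementations; the default is fixed by synthetic recovery and
    flippable for sensors/conventions that invert it.
    """
    x = np.asarray(vertical_accel, dtype=float)
    x = x - x.mean()
    if not np.any(x):
        return np.empty(0)
    z = cumulative_trapezoid(x, dx=1.0 / sample_rate, initial=0.0)
    fine = max(scale / fc_scale_divisor, 1.5)
    c2 = polarity * cwt_gaus2(cwt_gaus2(z, fine), fine)
    return _extrema_times(c2, sample_rate, refractory, FC_HEIGHT_FRACTION, minima=False)


def assemble_events(
    ic_times: np.ndarray, fc_times: np.ndarray, scale: float = np.nan
) -> GaitEvents:
    """Pair ICs with FCs and assign alternating laterality.

    Each IC is paired with the first FC after it and before the
    next-but-one IC — the contralateral toe-off that ends initial double
    support.  A second FC inside the same inter-IC interval violates the
    interleaving invariant and is dropped with a flag; unpairable ICs are
    retained with a flag.  Laterality alternates starting "L" (arbitrary;
    every downstream asymmetry measure is starting-label invariant).
    """
    ic = np.sort(np.asarray(ic_times, dtype=float))
    fc = np.sort(np.asarray(fc_times, dtype=float))
    flags: list[str] = []
    paired = np.full(ic.size, np.nan)
    used = np.zeros(fc.size, dtype=bool)
    for i in range(ic.size):
        hi = ic[i + 2] if i + 2 < ic.size else np.inf
        cand = np.nonzero((fc > ic[i]) & (fc < hi) & ~used)[0]
        if cand.size == 0:
            flags.append(f"ic[{i}]: unpaired")
            continue
        paired[i] = fc[cand[0]]
        used[cand[0]] = True
    # unused FCs inside the IC span violate IC/FC interleaving
    if ic.size:
        inside = ~used & (fc > ic[0]) & (fc < ic[-1])
        for j in np.nonzero(inside)[0]:
            flags.append(f"fc at {fc[j]:.3f}s: extra FC in interval, dropped")
    kept_fc = fc[used] if fc.size else fc
    sides = ["L" if i % 2 == 0 else "R" for i in range(ic.size)]
    return GaitEvents(
        ic_times=ic,
        fc_times=kept_fc,
        laterality=sides,
        cwt_scale=float(scale),
        paired_fc=paired,
        quality_flags=flags,
    )


def detect_events(
    vertical_accel: np.ndarray,
    sample_rate: float,
    scale: float | None = None,
    refractory: float = DEFAULT_REFRACTORY_S,
    fc_scale_divisor: float = DEFAULT_FC_SCALE_DIVISOR,
) -> GaitEvents:
    """Scale estimation + IC/FC detection + pairing for one segment."""
    if scale is None:
        scale = estimate_cwt_scale(vertical_accel, sample_rate)
    ic = detect_initial_contacts(vertical_accel, sample_rate, scale, refractory)
    fc = detect_final_contacts(
        vertical_accel, sample_rate, scale, refractory, fc_scale_divisor
    )
    return assemble_events(ic, fc, scale=scale)
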