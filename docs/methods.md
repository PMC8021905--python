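# Methods

This note records the models, conventions and design choices behind
`gaitfm`, in the order the pipeline runs. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic waveform model

The generator builds the vertical (cranio-caudal) acceleration of a lumbar
sensor analytically, so ground truth is exact rather than the output of an
ODE solver:

* **Centre-of-mass oscillation.** Within each step of duration *T* starting
  at an initial contact *t₀*, the vertical acceleration is
  `−A sin(2π(t−t₀)/T)` with `A = h(2π/T)²/2`. Its double integral over the
  step is a single sinusoidal arc with peak-to-trough excursion exactly
  *h* — the quantity the inverted-pendulum step-length model
  `L = 2√(2lh − h²)` consumes. *h* may differ by side to create spatial
  asymmetry.
* **Heel-strike transient.** A 30 ms raised-cosine pulse at each initial
  contact (default 0.15 g). PD gait tends to show attenuated heel strikes;
  the amplitude is configurable.
* **Toe-off transient.** An odd, Gaussian-derivative-shaped transient
  (σ = 20 ms, default 0.5 g) at each final contact. A final contact is only
  recoverable from a signal that actually carries a toe-off signature; this
  is the feature the FC detector keys on. Its odd symmetry makes it appear
  as a clean extremum after two wavelet differentiations while leaving the
  initial-contact channel essentially untouched.
* **Secondary channels.** Anteroposterior: a quarter-period-shifted copy of
  the oscillation at 40 % amplitude. Mediolateral: 0.05 g sway at stride
  frequency. Both are only used by the energy-based bout detector.
* Gravity (+1 g on the vertical axis), white sensor noise (default
  0.02 g — an AX3-class noise floor is a few mg RMS, so this is
  conservative; the study hardware's noise was never characterised, making
  this a free parameter), and clipping at ±8 g.

Final contacts are placed at `t_IC + s·(stride)` where *s* is the stance
fraction (default 0.60, the healthy textbook value; the PD cohort this
package models shows ≈ 0.75 — both are exercised in tests). Rest segments
are gravity + noise. `random_movement` segments are 3 Hz-low-passed noise
bursts (default 0.25 g per axis): energetic enough to trip the bout
threshold but with no locomotor periodicity, as false-positive bait.

What the generator does **not** emulate: turning, freezing-of-gait,
postural transitions, soft-tissue resonances, orientation drift, or the
harmonic richness of real gait spectra. Passing recovery tests therefore
demonstrates algorithmic correctness on signals satisfying the model's
assumptions, not clinical accuracy on patient data.

## Preprocessing

* Linear interpolation onto a uniform grid anchored at the first timestamp
  (no extrapolated samples); grid count `floor(span·rate) + 1`.
* Offset removal is whole-recording per-axis mean subtraction. A per-step
  re-centering happens again before integration in the parameter stage, so
  the global window choice is non-critical.
* The 17 Hz second-order Butterworth is applied forward–backward
  (`filtfilt`): event times must not be lag-shifted. The squared magnitude
  response puts the two-pass gain at the cutoff at 0.50 exactly; the test
  suite checks the implementation against the analytic response.
* The vertical axis is the one whose pre-subtraction mean is nearest ±1 g
  (must lie in [0.5, 1.5] g), signed positive-up. No sensor-fusion
  orientation tracking is attempted.

## Gait-event detection

The chain integrates the mean-centred vertical acceleration (cumulative
trapezoid) and differentiates it with a `gaus2` CWT:

* **Scale.** Estimated per segment from the spectral peak in the locomotor
  band (0.5–4 Hz): `scale = f_s · f_c(gaus2)/f*` with `f_c = 0.3`. The
  peak-versus-floor decision uses a Welch-averaged spectrum (a raw
  periodogram's noise peaks would occasionally pass any fixed ratio); the
  peak location uses the full-resolution periodogram. A segment with no
  peak ≥ 8× the in-band median floor raises "no locomotor band peak" —
  which doubles as the non-locomotor rejection in the free-living path.
* **Zero phase.** The wavelet is sampled from PyWavelets onto a symmetric
  odd-length grid and applied by centred convolution. (The library's own
  `cwt` differentiates an interpolated integral, which carries a sub-sample
  lag per pass — visible as a systematic ~10 ms event bias at 100 Hz.)
  Extrema are refined to sub-sample precision by parabolic interpolation.
* **Initial contacts** are minima of the first differentiation at the
  step-frequency scale, with a 0.25 s refractory period (below the shortest
  physiological step time at the 4 Hz band edge) and a height gate at 30 %
  of the largest extremum.
* **Final contacts** come from differentiating the integrated signal twice
  at a *finer* scale (`scale/4`). At the step-frequency scale the second
  differentiation of a near-sinusoidal signal has extrema at fixed phases
  of the cycle and carries no toe-off information; the sharp toe-off
  transient survives only at finer scales. Height gate 40 %.
* **Polarity.** Peak-polarity conventions differ between CWT
  implementations; both detectors expose a `polarity` flag whose default is
  fixed by synthetic recovery. One consequence of using an even wavelet on
  the *integrated* signal is that time reversal flips the coefficient sign,
  so analyses of reversed signals use the flipped polarity.
* **Pairing.** Each IC is paired with the first FC after it and before the
  next-but-one IC (the contralateral toe-off). A second FC inside one
  inter-IC interval violates interleaving and is dropped with a flag;
  unpairable events are flagged, never silently discarded.
* **Laterality** cannot be determined from a single vertical channel;
  labels alternate from an arbitrary "L". Every downstream asymmetry
  measure is an absolute left–right difference and therefore invariant to
  the starting label.

## Bout detection

* Free-living candidates: 2-s moving windows (stride 1 sample) where the
  summed per-axis sample SDs exceed 0.1. The published threshold is
  unitless; it is interpreted in g on the filtered, offset-removed signal
  (the device's native scale). Abutting active windows merge into maximal
  segments.
* Segments must exceed 5 s and contain ≥ 5 detected ICs; the first and last
  steps are trimmed (transition steps are not steady-state walking).
* A regularity gate rejects segments whose IC-interval coefficient of
  variation exceeds 0.25: real walking is near-periodic (bout-level step
  CV a few percent even in PD), while energetic non-locomotor movement is
  not. Together with the locomotor-peak check this enforces the
  precision-over-recall stance appropriate for free-living analysis — a
  false bout contaminates every parameter, a missed bout only loses data.
* Duration categories are half-open: [5, 15), [15, 30), [30, 60), [60, ∞)
  s. A bout of exactly 60 s belongs to the >60 s band (the alternative
  would contradict the "30 to 60" reading of the neighbouring band).
* Supervised trials bypass the energy detector entirely: the therapist's
  (optionally manually adjusted) trial interval minus reported pauses is
  authoritative.

## Gait parameters

Per step *i* with initial contacts `t_i`: step time `t_{i+1} − t_i`, stride
time `t_{i+2} − t_i`, stance time = (toe-off of foot *i*, i.e. the first FC
after `t_{i+1}`) − `t_i`, swing = stride − stance, and double support =
stance − step. Double support is reported as the **single** (terminal)
overlap interval per step, under which stance ≈ 75 % of the cycle implies
double support ≈ 25 % — the convention consistent with published PD panels;
the sum-of-both-overlaps convention would double it.

The vertical excursion *h* is the peak-to-trough of the twice-integrated,
per-step detrended vertical acceleration (converted to m/s² with
g = 9.81 exactly). Detrending is **endpoint-anchored**: the integration
constants contribute a pure line through the step's endpoints, which the
endpoint line removes exactly; a least-squares line fitted to a single
oscillation period has a systematically non-zero slope and biases the
excursion low by several percent. Steps with `h ≥ l` are flagged invalid,
excluded from all summaries and counted in logs. The pendulum length *l*
(sensor height) is a configuration input, default 0.9 m ≈ 0.53 × a 1.70 m
stature, since subject height is not carried by the recording.

Per-bout panel: central values are means over valid steps; cadence =
60 / mean step time; gait velocity = mean step velocity (free-living data
offer no external distance reference); swing% is computed as 100 − stance%
so the two sum to 100 identically. Variability is the SD of the per-step
series in native units, with coefficient-of-variation variants exported in
parallel (`*_cv`) — published panels are ambiguous between the two, so both
are carried and the SD is the default. Asymmetry is |mean(L) − mean(R)|.
Subject aggregates are step-count-weighted means within each bout category
(weighting by duration or equally is a one-line change); empty categories
are absent, never zero.

Step-count concurrent validity uses ICC(2,1) — two-way random effects,
absolute agreement, single measure — computed from the ANOVA mean squares.

## Clinical statistics

* Change from baseline is complete-case **per outcome** (not listwise),
  which is why *n* varies across outcomes; percent change is the magnitude
  of the mean change relative to the complete-case admission mean.
* Normality gate: Shapiro–Wilk at α = 0.05 decides paired *t* versus
  Wilcoxon signed-rank (exact for n ≤ 25 without ties, else normal
  approximation with continuity correction). The Lilliefors-corrected
  Kolmogorov–Smirnov statistic is reported alongside but is not decisive:
  with both tests listed and no arbitration rule stated anywhere,
  Shapiro–Wilk's better small-sample power makes it the natural gatekeeper.
* Paired Cohen's *d* = mean change / SD of change.
* Stepwise regression: classic forward selection with backward elimination
  on partial-F p-values, `p_enter = 0.05`, `p_remove = 0.10` (configurable;
  published single-predictor final models are insensitive to the exact
  criteria). Perfectly collinear candidates are excluded with a warning;
  entry stops when the fit is numerically perfect. Standardised β comes
  from z-scored response and predictor; VIF of a sole predictor is
  identically 1. Residual normality is checked with Shapiro–Wilk.
* Power analysis: the two-tailed one-sample (paired-difference) *t* power
  is computed from the noncentral-*t* distribution and the smallest *n*
  reaching the target power is found by iteration (with a normal-limit
  fallback where `nct.cdf` underflows). Results can differ by ±1 subject
  from other software's rounding conventions. The assumed effects are
  10/20/30 % of the baseline mean scaled by the observed SD of change.

## Problem sizes

Tests and the acceptance script use 30 s walking bouts at 100 Hz, grids of
10–20 gait profiles spanning step times 0.45–0.8 s and noise up to 0.05 g,
free-living schedules of ~5 activity segments × 6–10 days, 10 000-replicate
null simulations at n = 20 for test-size calibration, and synthetic cohorts
of 24 (matching the modelled study) or 10 000 (Monte-Carlo moments)
subjects. These sizes give Monte-Carlo error comfortably inside the
asserted tolerances while keeping the whole suite fast.

## Known limitations

* Detected step-time **asymmetry is attenuated**: the CWT smoothing at the
  step-frequency scale pulls alternating long/short intervals toward their
  mean, so a 20 ms systematic left–right offset survives event detection
  only partially. Asymmetry recovery is therefore validated at the
  step-table level (true events in, summary out); asymmetry from detected
  events should be treated as a lower bound.
* Step length inherits a small bias from transients inside the step window
  (≈ −2 % at the default profile; up to ≈ +6 % when a large toe-off
  transient lands mid-step, as at stance fractions near 0.75).
* The generator's spectra are far cleaner than real gait; detector height
  gates and the regularity threshold were chosen against it and may need
  retuning for real recordings.
* No turning detection, wear-time analysis, freezing detection, or
  left/right identification from AP/ML features.
* The power analysis assumes normally distributed changes even where the
  gated test selected Wilcoxon.
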