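# gaitfm

Lumbar-accelerometer gait analysis and functional-mobility statistics for
Parkinson's disease (PD) studies.

Functional mobility — a person's ability to move independently and safely
through daily tasks — is commonly assessed in PD with the Timed Up and Go
(TUG) test, but a single tri-axial accelerometer worn on the lower back (L5)
can measure it far more richly: spatiotemporal gait parameters during
supervised tests *and* during days of unsupervised free-living activity.
`gaitfm` implements that full measurement chain plus the clinical statistics
used to evaluate a rehabilitation intervention with it:

1. **Preprocessing** — linear-interpolation resampling to 100 Hz, offset
   removal, zero-phase 2nd-order Butterworth low-pass at 17 Hz, gravity-based
   vertical-axis identification.
2. **Walking-bout detection** — supervised trials from therapist annotations
   (pauses removed); free-living bouts from 2-s moving windows where the
   summed tri-axial SD exceeds 0.1 g, kept only if ≥ 5 s long with ≥ 5
   detected steps and near-periodic step intervals (precision over recall),
   then categorised into 5–15 s / 15–30 s / 30–60 s / >60 s bands.
3. **Gait events** — initial/final contacts by `gaus2`
   continuous-wavelet-transform differentiation of the integrated vertical
   acceleration, at a scale matched per segment to the dominant step
   frequency *f\** in 0.5–4 Hz (`scale = f_s · f_c / f*`).
4. **Gait parameters** — the 25-parameter panel per bout: velocities,
   cadence, step/stride lengths (inverted pendulum,
   `L = 2√(2lh − h²)` with vertical excursion *h* from double integration),
   phase durations and percentages, variability (SD) and left–right
   asymmetry; step-weighted per-subject aggregation by bout category.
5. **Clinical statistics** — change from baseline with a Shapiro–Wilk-gated
   paired *t* / Wilcoxon test, paired Cohen's *d* (= mean change / SD of
   change), stepwise multiple linear regression predicting TUG change (with
   VIF and residual-normality checks), and noncentral-*t* power analysis for
   10/20/30 % changes from baseline.

Because raw patient recordings from such studies are rarely shared, the
package ships a first-class **synthetic data module**: an analytic waveform
generator with exact ground-truth events, step lengths and bout intervals,
and a paired-cohort simulator with prescribed effect sizes and a known
sparse linear model. Every pipeline stage is validated against these
oracles.

## Worked example

```python
import numpy as np
from gaitfm import *
from gaitfm.parameters import compute_step_table
from gaitfm.evaluation import event_timing_errors

profile = GaitProfile(step_time_mean=0.6, step_time_sd=0.02, step_time_asym=0.02,
                      vertical_excursion_h=0.02, pendulum_length_l=0.9)
schedule = ActivitySchedule.single_walk(30.0, pad=5.0)
rec, truth = simulate_gait_recording(profile, schedule, seed=42)

uni = preprocess(rec)
vert = uni.vertical()[uni.index_at(5.0):uni.index_at(35.0)]
events = detect_events(vert, 100.0)
errs, frac = event_timing_errors(truth.ic_times - 5.0, events.ic_times)
panel = summarize_bout(compute_step_table(events, vert, 100.0, pendulum_length=0.9))
```

prints (via the obvious formatting):

```
true ICs: 50, detected: 49, median timing error: 9.0 ms
cadence         99.6 steps/min  (truth 99.7)
step length    0.371 m          (truth 0.377)
stance phase    60.8 %
```

The detector recovers the constructed heel strikes to within one sample or
two (9 ms at 100 Hz), and the inverted-pendulum step length lands within
2 % of the generator's closed-form value. On the clinical side, feeding the
published 24-patient summary statistics through the same code:

```python
from gaitfm.reference import TUG_NORMAL
cohens_d_paired(TUG_NORMAL.change_mean, TUG_NORMAL.change_sd)   # -0.24
sample_size_paired(TUG_NORMAL.admission_mean, TUG_NORMAL.change_sd, 30.0)
# d = 0.581, required n = 26 at alpha 0.05, power 0.80
```

i.e. the TUG detects only a small effect of the intervention (*d* = −0.24),
and a future trial powered to detect a 30 % TUG change from this baseline
would need 26 patients.

A CLI wraps the same functions: `gaitfm simulate`, `gaitfm extract`
(`--annotations` switches to the supervised path), `gaitfm bouts`,
`gaitfm stats`, `gaitfm power`.

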