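"""Published summary statistics used for worked examples and defaults.

Admission/discharge summaries of clinical outcomes from a 24-patient
Parkinson's disease cohort assessed before and after a specialized
multidisciplinary rehabilitation program (single lumbar accelerometer,
supervised + 3-day free-living protocol).  Only printed group-level
statistics are stored — no patient-level data.  They serve as:

* worked examples for the effect-size and percent-change computations,
* realistic defaults for the synthetic cohort generator,
* inputs to the power / sample-size grid.

``change_mean``/``change_sd`` are the complete-case paired change
(discharge − admission); ``n`` is the number of complete pairs, which
varies by outcome because not every patient completed every test.
"""
from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ClinicalOutcomeSummary", "CLINICAL_OUTCOMES", "TUG_NORMAL"]


@dataclass(frozen=True)
class ClinicalOutcomeSummary:
    name: str
    n: int
    admission_mean: float
    admission_sd: float
    discharge_mean: float
    discharge_sd: float
    change_mean: float
    change_sd: float
    improvement_direction: int  # -1: lower is better, +1: higher is better

    @property
    def cohens_d(self) -> float:
        """Paired effect size: mean change / SD of change."""
        return self.change_mean / self.change_sd

    @property
    def percent_change(self) -> float:
        """Magnitude of the mean change relative to the admission mean, %."""
        return abs(self.change_mean / self.admission_mean) * 100.0


CLINICAL_OUTCOMES: dict[str, ClinicalOutcomeSummary] = {
    s.name: s
    for s in [
        ClinicalOutcomeSummary("MDS-UPDRS I", 19, 13.95, 7.09, 8.25, 4.90, -5.53, 6.81, -1),
        ClinicalOutcomeSummary("MDS-UPDRS II", 19, 17.18, 9.24, 12.65, 7.04, -4.95, 10.02, -1),
        ClinicalOutcomeSummary("MDS-UPDRS III", 19, 39.36, 12.77, 32.20, 12.22, -8.52, 9.92, -1),
        ClinicalOutcomeSummary("MDS-UPDRS IV", 19, 1.95, 2.82, 1.35, 2.16, -0.21, 2.53, -1),
        ClinicalOutcomeSummary("MDS-UPDRS Total", 19, 72.45, 25.75, 54.45, 20.50, -19.26, 22.18, -1),
        ClinicalOutcomeSummary("Hoehn and Yahr", 24, 2.30, 0.93, 2.35, 0.71, 0.09, 0.68, -1),
        ClinicalOutcomeSummary("Schwab and England", 24, 73.75, 16.37, 75.83, 15.86, 2.08, 8.33, +1),
        ClinicalOutcomeSummary("TUG Normal", 24, 13.36, 7.27, 11.68, 4.75, -1.69, 6.90, -1),
        ClinicalOutcomeSummary("TUG Cognitive", 23, 17.22, 10.42, 14.10, 7.29, -2.80, 8.91, -1),
        ClinicalOutcomeSummary("TUG Manual", 19, 12.80, 5.21, 11.37, 4.35, -0.92, 8.69, -1),
        ClinicalOutcomeSummary("Mini-BESTest", 19, 20.19, 3.97, 20.70, 4.59, 0.63, 3.25, +1),
        ClinicalOutcomeSummary("5 STS Normal", 22, 19.36, 6.99, 14.29, 5.24, -4.31, 2.94, -1),
        ClinicalOutcomeSummary("5 STS Fast", 22, 17.56, 4.91, 13.25, 5.19, -5.07, 3.48, -1),
    ]
}

TUG_NORMAL = CLINICAL_OUTCOMES["TUG Normal"]
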