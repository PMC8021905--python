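"""Plain-text file formats: recordings, truth, annotations, outcomes.

Everything is CSV/JSON — the conversion target for the device's native
binary format, which is out of scope.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bouts import TrialAnnotation
from .preprocessing import RawRecording
from .synthetic import GroundTruth

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "read_annotations_json",
    "write_outcomes_csv",
    "read_outcomes_csv",
]

RECORDING_COLUMNS = ["time_s", "ax_g", "ay_g", "az_g"]


def write_recording_csv(rec: RawRecording, path: str | Path) -> None:
    frame = pd.DataFrame(
        np.column_stack([rec.timestamps, rec.accel]), columns=RECORDING_COLUMNS
    )
    frame.to_csv(path, index=False, float_format="%.6f")


def read_recording_csv(
    path: str | Path, nominal_rate: float = 100.0, dynamic_range: float = 8.0
) -> RawRecording:
    frame = pd.read_csv(path)
    missing = set(RECORDING_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"recording CSV missing columns {sorted(missing)}")
    return RawRecording(
        timestamps=frame["time_s"].to_numpy(),
        accel=frame[["ax_g", "ay_g", "az_g"]].to_numpy(),
        nominal_rate=nominal_rate,
        dynamic_range=dynamic_range,
    )


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def read_ground_truth_json(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        ic_times=np.asarray(d["ic_s"]),
        fc_times=np.asarray(d["fc_s"]),
        laterality=list(d["laterality"]),
        true_step_lengths=np.asarray(d["step_lengths_m"]),
        true_bout_intervals=[tuple(b) for b in d["bout_intervals_s"]],
        true_step_times=np.asarray(d.get("step_times_s", [])),
        stance_fraction=d.get("stance_fraction", 0.6),
    )


def read_annotations_json(path: str | Path) -> list[TrialAnnotation]:
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    return [TrialAnnotation.from_dict(d) for d in data]


def write_outcomes_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.4f")


def read_outcomes_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"subject_id", "outcome", "admission", "discharge"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"outcomes CSV missing columns {sorted(missing)}")
    return frame
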