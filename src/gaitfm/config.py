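"""Run configuration and stage logging.

A single flat-but-namespaced configuration object covers every stage; a
serialized copy (and its hash) is embedded in run outputs so results are
reproducible from the files alone.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

__all__ = ["RunConfig", "RunLog"]


@dataclass
class RunConfig:
    # preprocessing
    target_rate: float = 100.0
    cutoff_hz: float = 17.0
    filter_order: int = 2
    # bout detection
    bout_window_s: float = 2.0
    bout_threshold_g: float = 0.1
    min_bout_duration_s: float = 5.0
    min_ics: int = 5
    max_step_time_cv: float = 0.25  # free-living regularity gate (precision over recall)
    # event detection
    locomotor_band_hz: tuple[float, float] = (0.5, 4.0)
    refractory_s: float = 0.25
    fc_scale_divisor: float = 4.0
    # gait parameters
    pendulum_length_m: float = 0.9  # sensor height; default 0.53 × 1.70 m stature
    # clinical statistics
    p_enter: float = 0.05
    p_remove: float = 0.10
    alpha: float = 0.05
    power: float = 0.80
    # randomness
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_hz < self.target_rate / 2:
            raise ValueError("cutoff must lie below Nyquist")
        if self.min_ics < 2 or self.min_bout_duration_s <= 0:
            raise ValueError("invalid bout settings")
        if not (0 < self.p_enter <= self.p_remove < 1):
            raise ValueError("need 0 < p_enter <= p_remove < 1")
        self.locomotor_band_hz = tuple(self.locomotor_band_hz)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunLog:
    """Stage-granular accounting: counts in/out and rejects with reasons."""

    config_hash: str = ""
    seed: int | None = None
    records: list[dict] = field(default_factory=list)

    def stage(self, name: str, n_in: int, n_out: int, rejects: list[str] | None = None) -> None:
        self.records.append(
            {
                "time": datetime.now(timezone.utc).isoformat(),
                "stage": name,
                "n_in": n_in,
                "n_out": n_out,
                "rejects": rejects or [],
            }
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"config_hash": self.config_hash, "seed": self.seed, "stages": self.records},
                indent=1,
            )
        )
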