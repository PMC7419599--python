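"""Core in-memory containers shared across pipeline stages.

Streams are kept as plain :class:`pandas.DataFrame` objects with a ``time``
column in seconds, at each stream's native sampling rate — the trial-bundle
CSV files on disk mirror these frames column for column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import DataError

#: the 16-channel surface-EMG inventory (trunk, lower limbs, reaching arm)
MUSCLES = [
    "ES_L", "ES_R",          # erector spinae
    "RA_L", "RA_R",          # rectus abdominis
    "TA_L", "TA_R",          # tibialis anterior
    "GAS_L", "GAS_R",        # gastrocnemius
    "VL_L", "VL_R",          # vastus lateralis
    "BF_L", "BF_R",          # biceps femoris
    "DELT_A_R", "DELT_P_R",  # anterior / posterior deltoid, reaching arm
    "BIC_R", "TRI_R",        # biceps / triceps brachii, reaching arm
]

#: joint-angle channels (support-limb ankle, leading-limb hip)
JOINTS = ["ankle", "knee", "hip", "lumbar", "thorax", "shoulder", "elbow"]


@dataclass
class TrialMeta:
    participant: str
    group: str
    condition: str
    trial_index: int
    vas_likely_mm: float
    vas_concern_mm: float
    body_mass_kg: float
    rates: dict[str, float] = field(default_factory=dict)
    plate_centers: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"L": (0.0, 0.12), "R": (0.0, -0.12)}
    )

    @property
    def trial_id(self) -> str:
        return f"{self.participant}_{self.condition}_t{self.trial_index}"


@dataclass
class TrialRecording:
    """Raw multi-rate channel bundle for one step-and-reach trial."""

    meta: TrialMeta
    emg: pd.DataFrame       # time + one column per muscle
    force: pd.DataFrame     # time + fx,fy,fz,mx,my,mz per plate (suffix _L/_R)
    kin: pd.DataFrame       # time + com_x/y/z + joint angles + malleoli
    sensor: pd.DataFrame    # time + beam (0/1)


@dataclass
class TrialGroundTruth:
    """Generator-side truth paired with each synthetic trial."""

    events: dict[str, float]                 # reach_on/reach_off/cop_on/step_on/step_off
    muscle_onsets: dict[str, float]          # absolute onset time per muscle
    metrics: dict[str, float]                # per-metric true values
    vas_likely_mm: float = 0.0
    vas_concern_mm: float = 0.0


@dataclass
class EventSet:
    """Per-trial timeline anchoring all downstream metrics (seconds)."""

    reach_on: float
    reach_off: float
    cop_on: Optional[float]
    step_on: float
    step_off: float
    cop_axis: str = ""
    flags: list[str] = field(default_factory=list)

    def validate(self, duration_s: Optional[float] = None) -> None:
        if not self.reach_off > self.reach_on:
            raise DataError("reach_off must follow reach_on")
        if not self.step_on < self.step_off:
            raise DataError("step_off must follow step_on")
        if self.cop_on is not None and self.cop_on > self.step_on:
            # kept analyzable, but flagged: preparation should precede unloading
            if "cop_after_step" not in self.flags:
                self.flags.append("cop_after_step")
        if duration_s is not None:
            for name in ("reach_on", "reach_off", "step_on", "step_off"):
                t = getattr(self, name)
                if not 0.0 <= t <= duration_s:
                    raise DataError(f"event {name}={t:.3f}s outside [0, {duration_s}]")


@dataclass
class StepCharacteristics:
    step_length_m: float
    step_width_m: float
    step_time_s: float

    def __post_init__(self) -> None:
        if self.step_time_s <= 0:
            raise DataError("step_time must be positive")
        if self.step_length_m < 0 or self.step_width_m < 0:
            raise DataError("step length/width must be non-negative")


@dataclass
class EmgResult:
    """Per-muscle onsets (absolute and reach-relative) and per-pair CCI."""

    onsets_s: dict[str, Optional[float]]
    latencies_s: dict[str, Optional[float]]
    cci: dict[tuple[str, str], float]        # (pair region, phase) -> value
    flags: list[str] = field(default_factory=list)


@dataclass
class MovementMetrics:
    prep_com_acc_ap: float
    prep_com_acc_ml: float
    prep_com_exc_ap: float
    prep_com_exc_ml: float
    total_com_exc_ap: float
    total_com_exc_ml: float
    joint_excursions_deg: dict[str, float]
    step: Optional[StepCharacteristics] = None
    flags: list[str] = field(default_factory=list)
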