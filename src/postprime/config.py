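"""Configuration models for the step-and-reach analysis pipeline.

Every tunable of the pipeline lives in one of the pydantic models below, and
the whole pipeline configuration serializes to / from a single YAML document
(see :class:`PipelineConfig`).  Unknown keys are rejected so that typos in a
config file fail loudly instead of silently using defaults.
"""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import ConfigError


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


# ---------------------------------------------------------------------------
# signal conditioning


class FilterSpec(_Model):
    """Preprocessing chain parameters.

    Kinematics are smoothed with a Savitzky–Golay filter and the quiet-stance
    DC offset is removed.  EMG is notch filtered at mains frequency, demeaned,
    full-wave rectified and low-pass filtered with a zero-lag Butterworth
    (realized as a forward–backward pass of a half-order design, so the
    effective order equals ``lp_order``).
    """

    sg_window: int = 40          # samples of the stream it is applied to
    sg_polyorder: int = 3
    notch_hz: float = 60.0
    notch_q: float = 30.0
    lp_cutoff_hz: float = 100.0
    lp_order: int = 4            # effective (forward+backward) order
    dc_baseline_s: float = 0.5   # quiet-stance window used for DC removal

    @model_validator(mode="after")
    def _check(self) -> "FilterSpec":
        if self.sg_window <= self.sg_polyorder:
            raise ConfigError("sg_window must exceed sg_polyorder")
        if self.lp_order <= 0 or self.lp_order % 2:
            raise ConfigError("lp_order must be a positive even integer")
        if min(self.notch_hz, self.notch_q, self.lp_cutoff_hz) <= 0:
            raise ConfigError("filter frequencies and Q must be positive")
        return self


# ---------------------------------------------------------------------------
# EMG onset detection / co-contraction


class OnsetParams(_Model):
    """Threshold-and-sustain muscle onset criterion.

    Onset is the first sample whose envelope exceeds
    ``baseline mean + k_sd * baseline SD`` and stays above that threshold for
    ``sustain_s`` seconds.
    """

    k_sd: float = 7.0
    sustain_s: float = 0.050
    baseline_window: tuple[float, float] = (0.0, 0.5)

    @model_validator(mode="after")
    def _check(self) -> "OnsetParams":
        if self.k_sd <= 0:
            raise ConfigError("k_sd must be positive")
        if self.sustain_s <= 0:
            raise ConfigError("sustain_s must be positive")
        if self.baseline_window[1] <= self.baseline_window[0]:
            raise ConfigError("baseline_window must have positive length")
        return self


class CciPhases(_Model):
    """The four co-contraction windows, anchored to reach onset/offset.

    Phases i–iii are offsets from reach onset, phase iv from target contact:
    (i) early, 1.5–0.5 s before reach onset; (ii) preparatory, the 0.5 s
    before reach onset; (iii) movement, the 0.5 s after reach onset;
    (iv) termination, the 0.5 s before target contact.
    """

    early: tuple[float, float] = (-1.5, -0.5)
    preparatory: tuple[float, float] = (-0.5, 0.0)
    movement: tuple[float, float] = (0.0, 0.5)
    termination: tuple[float, float] = (-0.5, 0.0)   # relative to reach_off

    def windows(self, reach_on: float, reach_off: float) -> dict[str, tuple[float, float]]:
        """Absolute (start, end) windows for phases i–iv on the trial clock."""
        win = {
            "i": (reach_on + self.early[0], reach_on + self.early[1]),
            "ii": (reach_on + self.preparatory[0], reach_on + self.preparatory[1]),
            "iii": (reach_on + self.movement[0], reach_on + self.movement[1]),
            "iv": (reach_off + self.termination[0], reach_off + self.termination[1]),
        }
        for name, (a, b) in win.items():
            if b <= a:
                raise ConfigError(f"CCI phase {name} window is empty")
        return win


class MusclePair(_Model):
    agonist: str
    antagonist: str
    region: str = ""


DEFAULT_PAIRS = [
    MusclePair(agonist="RA_L", antagonist="ES_L", region="trunk_left"),
    MusclePair(agonist="RA_R", antagonist="ES_R", region="trunk_right"),
    MusclePair(agonist="TA_L", antagonist="GAS_L", region="shank_left"),
    MusclePair(agonist="TA_R", antagonist="GAS_R", region="shank_right"),
]


class CciConfig(_Model):
    method: str = "weighted"        # "weighted" (amplitude-weighted) or "ratio"
    phases: CciPhases = Field(default_factory=CciPhases)
    pairs: list[MusclePair] = Field(default_factory=lambda: list(DEFAULT_PAIRS))

    @field_validator("method")
    @classmethod
    def _method(cls, v: str) -> str:
        if v not in ("weighted", "ratio"):
            raise ConfigError(f"cci.method must be 'weighted' or 'ratio', got {v!r}")
        return v


# ---------------------------------------------------------------------------
# event detection


class EventParams(_Model):
    """Thresholds for CoP-onset and force-plate step-event detection.

    The source text of the protocol never states these algorithms; the
    defaults below are standard posturography heuristics and every one of
    them is configurable.
    """

    cop_k_sd: float = 3.0
    cop_sustain_s: float = 0.025
    cop_refine: str = "hinge"         # "hinge" (changepoint fit) or "threshold"
    cop_refine_back_s: float = 0.80
    cop_refine_fwd_s: float = 0.10
    unload_frac: float = 0.05         # fraction of quiet-stance limb load
    load_frac_bw: float = 0.05        # fraction of body weight at landing
    step_sustain_s: float = 0.005
    baseline_window: tuple[float, float] = (0.0, 0.5)

    @field_validator("cop_refine")
    @classmethod
    def _refine(cls, v: str) -> str:
        if v not in ("hinge", "threshold"):
            raise ConfigError(f"events.cop_refine must be 'hinge' or 'threshold', got {v!r}")
        return v

    @model_validator(mode="after")
    def _check(self) -> "EventParams":
        if self.baseline_window[1] - self.baseline_window[0] < 0.5:
            raise ConfigError("events.baseline_window must be at least 0.5 s long")
        return self


class MovementParams(_Model):
    """Interval conventions for the movement metrics."""

    movement_end: str = "reach_off"   # end of the "duration of movement"
    min_prep_samples: int = 3

    @field_validator("movement_end")
    @classmethod
    def _end(cls, v: str) -> str:
        if v not in ("reach_off", "trial_end"):
            raise ConfigError("movement.movement_end must be 'reach_off' or 'trial_end'")
        return v


# ---------------------------------------------------------------------------
# statistics


class FamilySpec(_Model):
    """A family of dependent variables sharing one divided-alpha correction.

    ``alpha_adj = 0.05 / (len(dvs) * 2)`` — each DV contributes a condition
    main effect and a condition × group interaction to the family.
    """

    name: str
    dvs: list[str]

    @field_validator("dvs")
    @classmethod
    def _nonempty(cls, v: list[str]) -> list[str]:
        if not v:
            raise ConfigError("family needs at least one DV")
        return v

    @property
    def n_tests(self) -> int:
        return 2 * len(self.dvs)

    @property
    def alpha_adj(self) -> float:
        return 0.05 / self.n_tests


class StatsConfig(_Model):
    method: str = "divided_alpha"     # "divided_alpha" (as published) or "holm_sequential"
    alpha: float = 0.05
    gg: str = "auto"                  # "auto" (Mauchly-gated), "always", "never"

    @field_validator("method")
    @classmethod
    def _method(cls, v: str) -> str:
        if v not in ("divided_alpha", "holm_sequential"):
            raise ConfigError("stats.method must be 'divided_alpha' or 'holm_sequential'")
        return v

    @field_validator("gg")
    @classmethod
    def _gg(cls, v: str) -> str:
        if v not in ("auto", "always", "never"):
            raise ConfigError("stats.gg must be 'auto', 'always' or 'never'")
        return v


# ---------------------------------------------------------------------------
# synthetic cohort


class EffectSpec(_Model):
    """Generative model for one scalar metric.

    value = baseline + condition[c] + group[g] + interaction["G:C"]
            + N(0, subject_sd) per participant + N(0, noise_sd) per trial.
    """

    baseline: float
    condition: dict[str, float] = Field(default_factory=dict)
    group: dict[str, float] = Field(default_factory=dict)
    interaction: dict[str, float] = Field(default_factory=dict)
    subject_sd: float = 0.0
    noise_sd: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "EffectSpec":
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ConfigError("effect SDs must be non-negative")
        return self

    def mean(self, group: str, condition: str) -> float:
        return (
            self.baseline
            + self.condition.get(condition, 0.0)
            + self.group.get(group, 0.0)
            + self.interaction.get(f"{group}:{condition}", 0.0)
        )


class NoiseConfig(_Model):
    """Per-channel measurement-noise SDs; ``noise_scale`` scales all of them
    (and every per-trial metric noise) jointly, so ``noise_scale=0`` yields
    noise-free recordings while keeping between-participant heterogeneity."""

    emg_baseline_sd: float = 0.10    # normalized EMG units
    force_sd_n: float = 2.0
    moment_sd_nm: float = 0.7
    com_sd_m: float = 0.002
    joint_sd_deg: float = 0.25
    malleolus_sd_m: float = 0.002
    noise_scale: float = 1.0

    @model_validator(mode="after")
    def _check(self) -> "NoiseConfig":
        for name in ("emg_baseline_sd", "force_sd_n", "moment_sd_nm", "com_sd_m",
                     "joint_sd_deg", "malleolus_sd_m", "noise_scale"):
            if getattr(self, name) < 0:
                raise ConfigError(f"noise.{name} must be non-negative")
        return self


class CohortSpec(_Model):
    """Design of a synthetic step-and-reach cohort.

    The defaults reproduce the study conditions: 2 age groups x 10
    participants, four surface conditions presented in blocked order
    NL -> LP -> LL -> LB, 3 trials per condition block, 8 s recordings with
    EMG at 2000 Hz, force plates at 1000 Hz and kinematics at 100 Hz.
    """

    n_per_group: int = 10
    groups: tuple[str, ...] = ("YOUNG", "OLDER")
    conditions: tuple[str, ...] = ("NL", "LP", "LL", "LB")
    trials_per_condition: int = 3
    duration_s: float = 8.0
    emg_rate_hz: float = 2000.0
    force_rate_hz: float = 1000.0
    kin_rate_hz: float = 100.0
    body_mass_kg: float = 69.5
    body_mass_sd_kg: float = 9.5
    carrier_hz: float = 250.0
    effects: dict[str, EffectSpec] = Field(default_factory=dict)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        for name in ("emg_rate_hz", "force_rate_hz", "kin_rate_hz"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2 (within-group variance is needed)")
        if self.trials_per_condition < 1:
            raise ConfigError("trials_per_condition must be >= 1")
        if len(self.conditions) < 2:
            raise ConfigError("conditions must list at least two labels")
        return self

    @property
    def n_trials(self) -> int:
        return (self.n_per_group * len(self.groups)
                * len(self.conditions) * self.trials_per_condition)


# ---------------------------------------------------------------------------
# pipeline


class PipelineConfig(_Model):
    """One YAML document describing a full simulate -> analyze run."""

    cohort: CohortSpec = Field(default_factory=CohortSpec)
    filters: FilterSpec = Field(default_factory=FilterSpec)
    onset: OnsetParams = Field(default_factory=OnsetParams)
    events: EventParams = Field(default_factory=EventParams)
    cci: CciConfig = Field(default_factory=CciConfig)
    movement: MovementParams = Field(default_factory=MovementParams)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    families: Optional[list[FamilySpec]] = None   # None -> default families
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)


def load_pipeline_config(path: str) -> PipelineConfig:
    """Load and validate a pipeline config; unknown keys are rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except ConfigError:
        raise
    except Exception as exc:  # pydantic ValidationError -> ConfigError
        raise ConfigError(str(exc)) from exc
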