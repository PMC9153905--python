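"""Configuration models for task, participants, clock, scoring and studies.

All models are pydantic so that YAML/JSON study files are validated on
load.  Defaults mirror the web-based stop-signal task being modelled:
a 32-trial practice block plus three 64-trial experimental blocks, 25%
stop trials, an SSD staircase starting at 250 ms moving in 50 ms steps,
1000 ms stimulus presentation, and practice/experimental inter-trial
intervals of 4250/2250 ms.
"""

from __future__ import annotations

import enum
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class ConfigurationError(ValueError):
    """Raised when a configuration is internally inconsistent."""


class SessionConfig(BaseModel):
    """Structure and timing of one task session."""

    model_config = ConfigDict(validate_assignment=True)

    n_practice_trials: int = Field(32, ge=0)
    n_experimental_blocks: int = Field(3, ge=1)
    trials_per_block: int = Field(64, ge=1)
    stop_fraction: float = Field(0.25, ge=0.0, le=1.0)
    initial_ssd: float = Field(250.0, ge=0.0)
    ssd_step: float = Field(50.0, gt=0.0)
    ssd_floor: float = Field(0.0, ge=0.0)
    ssd_ceiling: float = Field(950.0, gt=0.0)
    stimulus_duration: float = Field(1000.0, gt=0.0)
    fixation_duration: float = Field(250.0, gt=0.0)
    blank_duration: float = Field(1000.0, gt=0.0)
    practice_feedback_duration: float = Field(2000.0, gt=0.0)
    slow_rt_threshold: float = Field(500.0, gt=0.0)
    consecutive_omission_warning: int = Field(3, ge=1)
    # staircase carries from practice into experimental blocks if True;
    # default resets to initial_ssd at the start of experimental block 1
    carry_practice_ssd: bool = False
    # if True, the no-consecutive-stops rule also spans block boundaries
    stops_span_blocks: bool = False
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "SessionConfig":
        n_stop = self.stop_fraction * self.trials_per_block
        if abs(n_stop - round(n_stop)) > 1e-9:
            raise ConfigurationError(
                f"stop_fraction × trials_per_block = {n_stop} is not an integer"
            )
        if self.n_practice_trials:
            n_stop_p = self.stop_fraction * self.n_practice_trials
            if abs(n_stop_p - round(n_stop_p)) > 1e-9:
                raise ConfigurationError(
                    f"stop_fraction × n_practice_trials = {n_stop_p} is not an integer"
                )
        if not (self.ssd_floor <= self.initial_ssd <= self.ssd_ceiling):
            raise ConfigurationError(
                f"initial_ssd {self.initial_ssd} outside "
                f"[{self.ssd_floor}, {self.ssd_ceiling}]"
            )
        if self.ssd_floor >= self.ssd_ceiling:
            raise ConfigurationError("ssd_floor must be below ssd_ceiling")
        return self

    @property
    def practice_iti(self) -> float:
        """Practice inter-trial interval (blank + fixation + stimulus + feedback)."""
        return (
            self.blank_duration
            + self.fixation_duration
            + self.stimulus_duration
            + self.practice_feedback_duration
        )

    @property
    def experimental_iti(self) -> float:
        """Experimental inter-trial interval (blank + fixation + stimulus)."""
        return self.blank_duration + self.fixation_duration + self.stimulus_duration

    @property
    def n_experimental_trials(self) -> int:
        return self.n_experimental_blocks * self.trials_per_block

    @property
    def n_trials(self) -> int:
        return self.n_practice_trials + self.n_experimental_trials


class ParticipantParams(BaseModel):
    """Latent racer parameters for one participant-session.

    Go RTs are ex-Gaussian (Normal(go_mu, go_sigma) + Exponential(go_tau));
    the stop process latency is Normal(stop_mu, stop_sigma).  On a stop
    trial a response escapes inhibition iff the go process finishes before
    stop-signal onset + stop latency (independent horse race), or with
    probability ``p_trigger_failure`` the stop process never launches.
    """

    model_config = ConfigDict(validate_assignment=True)

    go_mu: float = Field(420.0, gt=0.0)
    go_sigma: float = Field(45.0, ge=0.0)
    go_tau: float = Field(70.0, ge=0.0)
    stop_mu: float = Field(240.0, gt=0.0)
    stop_sigma: float = Field(30.0, ge=0.0)
    p_trigger_failure: float = Field(0.0, ge=0.0, le=1.0)
    p_go_omission: float = Field(0.0, ge=0.0, le=1.0)
    p_choice_error: float = Field(0.0, ge=0.0, le=1.0)

    @property
    def mean_go_rt(self) -> float:
        """Ex-Gaussian mean: mu + tau."""
        return self.go_mu + self.go_tau


class ClockModel(BaseModel):
    """Timing error between the programmed SSD and the real-time-clock one.

    The measured ("meta") SSD is programmed + Normal(offset_mean,
    offset_sd), optionally quantized to a frame duration, clamped at 0.
    ``quantum = 0`` disables quantization.
    """

    offset_mean: float = 0.0
    offset_sd: float = Field(0.0, ge=0.0)
    quantum: float = Field(0.0, ge=0.0)


class Order(str, enum.Enum):
    INDEPENDENT_FIRST = "independent_first"
    LAB_FIRST = "lab_first"
    COUNTERBALANCED = "counterbalanced"


class FieldDist(BaseModel):
    """Cohort-level Normal(mean, sd) for one participant parameter."""

    mean: float
    sd: float = Field(0.0, ge=0.0)


class CohortParams(BaseModel):
    """Cohort generator for a two-condition (lab vs independent) study.

    Per-participant parameters are drawn from the cohort Normals; the
    latent stop latency is drawn jointly for the two sessions with the
    configured cross-session correlation, which is what makes the
    estimated SSRT test-retest correlation positive.  The independent
    condition adds ``condition_effect_ssrt`` ms to the stop latency and
    ``condition_effect_go_error`` to the choice-error probability.

    Defaults emulate a healthy young-adult cohort: mean go RT ≈ 490 ms
    with within-session SD ≈ 83 ms, SSRT ≈ 240 ms, ~1.4% go errors and
    ~0.6% go omissions.
    """

    model_config = ConfigDict(validate_assignment=True)

    n_participants: int = Field(123, ge=2)
    go_mu: FieldDist = FieldDist(mean=420.0, sd=55.0)
    go_sigma: FieldDist = FieldDist(mean=45.0, sd=8.0)
    go_tau: FieldDist = FieldDist(mean=70.0, sd=15.0)
    stop_mu: FieldDist = FieldDist(mean=240.0, sd=35.0)
    stop_sigma: FieldDist = FieldDist(mean=30.0, sd=5.0)
    p_trigger_failure: FieldDist = FieldDist(mean=0.0, sd=0.0)
    p_go_omission: FieldDist = FieldDist(mean=0.006, sd=0.006)
    p_choice_error: FieldDist = FieldDist(mean=0.014, sd=0.010)
    session_correlation: float = Field(0.6, ge=-1.0, le=1.0)
    condition_effect_ssrt: float = 22.0
    condition_effect_go_error: float = 0.008
    order: Order = Order.COUNTERBALANCED


class ScoringOptions(BaseModel):
    """Options for session scoring.

    ``ssd_source`` selects which SSD mean enters the mean-method SSRT
    (the real-time-clock "meta" delay by default).  The main go-RT mean
    uses correct responses only unless ``include_go_errors_in_rt`` is
    set; error RTs are always reported separately as well.
    """

    ssd_source: Literal["meta", "programmed"] = "meta"
    include_go_errors_in_rt: bool = False


class StudyConfig(BaseModel):
    """End-to-end study: cohort, task, clock, scoring and the master seed.

    Every per-participant, per-session random stream is derived from
    ``master_seed`` with a counter-based spawn key (participant index,
    session index), so adding participants never perturbs earlier streams.
    """

    session: SessionConfig = SessionConfig()
    cohort: CohortParams = CohortParams()
    clock: ClockModel = ClockModel(offset_mean=2.5, offset_sd=2.0)
    scoring: ScoringOptions = ScoringOptions()
    master_seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Load a study configuration from a YAML or JSON file."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        return cls.model_validate(data or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=False)
        )
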