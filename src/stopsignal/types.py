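"""Core trial-level data structures for the stop-signal task.

A session is a sequence of trials.  Each trial is either a *go* trial
(respond to an X or O as fast as possible) or a *stop* trial (a stop
signal follows the go stimulus after the current stop-signal delay, and
the response must be withheld).  These types carry the planned trial
(:class:`TrialSpec`), the adaptive-staircase bookkeeping
(:class:`StaircaseState`), the simulated outcome (:class:`TrialResult`)
and the feedback the task would display (:class:`FeedbackEvent`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Optional


class Block(str, enum.Enum):
    PRACTICE = "practice"
    EXP1 = "exp1"
    EXP2 = "exp2"
    EXP3 = "exp3"

    @staticmethod
    def experimental(i: int) -> "Block":
        """Block enum for 1-based experimental block index."""
        return Block(f"exp{i}")


class TrialType(str, enum.Enum):
    GO = "go"
    STOP = "stop"


class Stimulus(str, enum.Enum):
    X = "X"
    O = "O"


class Outcome(str, enum.Enum):
    GO_CORRECT = "go_correct"
    GO_ERROR = "go_error"              # wrong key on a go trial
    GO_OMISSION = "go_omission"        # no response within the window
    STOP_INHIBITED = "stop_inhibited"
    STOP_FAILED_CORRECT_KEY = "stop_failed_correct_key"
    STOP_FAILED_INCORRECT_KEY = "stop_failed_incorrect_key"


GO_OUTCOMES = frozenset({Outcome.GO_CORRECT, Outcome.GO_ERROR, Outcome.GO_OMISSION})
STOP_OUTCOMES = frozenset(
    {
        Outcome.STOP_INHIBITED,
        Outcome.STOP_FAILED_CORRECT_KEY,
        Outcome.STOP_FAILED_INCORRECT_KEY,
    }
)


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial: position, block, type and go stimulus."""

    index: int
    block: Block
    trial_type: TrialType
    go_stimulus: Stimulus


@dataclass(frozen=True)
class StaircaseState:
    """State of the 1-up/1-down tracking procedure for the stop-signal delay.

    Successful inhibitions raise the SSD by ``step`` (making stopping
    harder), failed inhibitions lower it, clamped to [floor, ceiling].
    The rule converges on the delay at which stopping succeeds ~50% of
    the time.
    """

    current_ssd: float
    step: float
    floor: float
    ceiling: float
    n_updates: int = 0

    def __post_init__(self) -> None:
        if not (self.floor <= self.current_ssd <= self.ceiling):
            raise ValueError(
                f"SSD {self.current_ssd} outside [{self.floor}, {self.ceiling}]"
            )

    def updated(self, inhibited: bool) -> "StaircaseState":
        """Return the next state after one stop trial."""
        if inhibited:
            ssd = min(self.current_ssd + self.step, self.ceiling)
        else:
            ssd = max(self.current_ssd - self.step, self.floor)
        return replace(self, current_ssd=ssd, n_updates=self.n_updates + 1)


@dataclass(frozen=True)
class TrialResult:
    """Simulated outcome of one trial.

    ``ssd_programmed`` is the staircase-scheduled stop-signal delay;
    ``ssd_meta`` is the delay as it would be measured by the machine's
    real-time clock (programmed value plus timing error).  Both are
    present only on stop trials.  ``rt`` is present iff a response was
    made.
    """

    spec: TrialSpec
    responded: bool
    outcome: Outcome
    rt: Optional[float] = None
    response_key: Optional[Stimulus] = None
    ssd_programmed: Optional[float] = None
    ssd_meta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.responded != (self.rt is not None):
            raise ValueError("rt must be present iff responded")
        if self.responded != (self.response_key is not None):
            raise ValueError("response_key must be present iff responded")
        is_stop = self.spec.trial_type is TrialType.STOP
        if is_stop != (self.ssd_programmed is not None) or is_stop != (
            self.ssd_meta is not None
        ):
            raise ValueError("SSD fields must be present iff the trial is a stop trial")
        if is_stop and self.outcome not in STOP_OUTCOMES:
            raise ValueError(f"{self.outcome} invalid for a stop trial")
        if not is_stop and self.outcome not in GO_OUTCOMES:
            raise ValueError(f"{self.outcome} invalid for a go trial")
        if self.rt is not None and self.rt <= 0:
            raise ValueError("rt must be positive")
        # key accord: 'correct key' means the pressed key matches the stimulus
        if self.outcome in (Outcome.GO_CORRECT, Outcome.STOP_FAILED_CORRECT_KEY):
            if self.response_key != self.spec.go_stimulus:
                raise ValueError(f"{self.outcome} requires response_key == go_stimulus")
        if self.outcome in (Outcome.GO_ERROR, Outcome.STOP_FAILED_INCORRECT_KEY):
            if self.response_key == self.spec.go_stimulus:
                raise ValueError(f"{self.outcome} requires response_key != go_stimulus")
        if self.outcome in (Outcome.GO_OMISSION, Outcome.STOP_INHIBITED):
            if self.responded:
                raise ValueError(f"{self.outcome} requires no response")


class MessageId(str, enum.Enum):
    # screens shown on every practice trial
    GET_READY = "get_ready"
    GO_PROMPT = "go_prompt"
    STOP_PROMPT = "stop_prompt"
    WAIT = "wait"
    # per-trial practice outcome feedback
    HIT = "hit"
    HIT_TOO_SLOW = "hit_too_slow"
    MISS_OMISSION = "miss_omission"
    MISS_INCORRECT = "miss_incorrect"
    STOP_SUCCESS = "stop_success"
    STOP_FAIL = "stop_fail"
    # fires after every 3rd consecutive go omission (practice + experimental)
    OMISSION_WARNING = "omission_warning"
    # end-of-block summary items
    SUMMARY_GO_ERRORS = "summary_go_errors"
    SUMMARY_GO_MISSES = "summary_go_misses"
    SUMMARY_MEAN_RT = "summary_mean_rt"
    SUMMARY_STOP_PCT = "summary_stop_pct"
    SUMMARY_COUNTDOWN = "summary_countdown"


class Color(str, enum.Enum):
    WHITE = "white"
    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"


@dataclass(frozen=True)
class FeedbackEvent:
    """One feedback message the task would display."""

    trial_index: int
    message_id: MessageId
    color: Color
    payload: Mapping[str, Any] = field(default_factory=dict)
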