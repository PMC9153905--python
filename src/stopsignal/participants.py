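"""Synthetic participants: the independent horse-race response generator
and a cohort generator with cross-session structure.

The racer follows the independent horse-race account of stopping: on a
stop trial the go process (ex-Gaussian finishing time) races the stop
process (Normal latency launched at stop-signal onset).  The response
escapes inhibition iff the go process finishes first; otherwise the
trial is successfully inhibited.  Trigger failures (the stop process
never launching) are supported but default off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ClockModel, CohortParams, ParticipantParams, Order
from .types import Outcome, Stimulus

__all__ = [
    "GoResponse",
    "StopResponse",
    "CohortMember",
    "sample_go_rt",
    "sample_go_response",
    "sample_stop_outcome",
    "apply_clock",
    "sample_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
]


@dataclass(frozen=True)
class GoResponse:
    """Outcome of the go process on a go trial."""

    responded: bool
    rt: Optional[float]
    response_key: Optional[Stimulus]
    outcome: Outcome


@dataclass(frozen=True)
class StopResponse:
    """Outcome of the go/stop race on a stop trial."""

    responded: bool
    rt: Optional[float]
    response_key: Optional[Stimulus]
    outcome: Outcome


def sample_go_rt(params: ParticipantParams, rng: np.random.Generator) -> float:
    """One ex-Gaussian go finishing time (ms), untruncated."""
    rt = rng.normal(params.go_mu, params.go_sigma)
    if params.go_tau > 0:
        rt += rng.exponential(params.go_tau)
    return rt


def _choose_key(
    stimulus: Stimulus, params: ParticipantParams, rng: np.random.Generator
) -> Stimulus:
    if rng.random() < params.p_choice_error:
        return Stimulus.O if stimulus is Stimulus.X else Stimulus.X
    return stimulus


def sample_go_response(
    params: ParticipantParams,
    stimulus: Stimulus,
    rng: np.random.Generator,
    window: float = 1000.0,
) -> GoResponse:
    """Simulate one go trial.

    With probability ``p_go_omission`` the trial is an omission outright;
    otherwise the ex-Gaussian go RT is drawn, and RTs beyond the response
    window (the stimulus presentation) also count as omissions.  A
    response uses the wrong key with probability ``p_choice_error``.
    """
    if rng.random() < params.p_go_omission:
        return GoResponse(False, None, None, Outcome.GO_OMISSION)
    rt = sample_go_rt(params, rng)
    if rt <= 0 or rt > window:
        return GoResponse(False, None, None, Outcome.GO_OMISSION)
    key = _choose_key(stimulus, params, rng)
    outcome = Outcome.GO_CORRECT if key is stimulus else Outcome.GO_ERROR
    return GoResponse(True, float(rt), key, outcome)


def sample_stop_outcome(
    params: ParticipantParams,
    ssd: float,
    stimulus: Stimulus,
    rng: np.random.Generator,
    window: float = 1000.0,
) -> StopResponse:
    """Simulate one stop trial at stop-signal delay ``ssd`` (ms).

    Race rule: the response escapes iff the go finishing time is below
    ssd + stop latency (and within the response window).  With
    probability ``p_trigger_failure`` the stop process never starts, so
    any in-window go finish produces a response.  The go process can
    also fail outright (``p_go_omission``), which yields a (trivially)
    inhibited trial.
    """
    if ssd < 0:
        raise ValueError("ssd must be non-negative")
    if rng.random() < params.p_go_omission:
        return StopResponse(False, None, None, Outcome.STOP_INHIBITED)
    go_finish = sample_go_rt(params, rng)
    in_window = 0 < go_finish <= window
    if rng.random() < params.p_trigger_failure:
        escapes = in_window
    else:
        stop_finish = ssd + rng.normal(params.stop_mu, params.stop_sigma)
        escapes = in_window and go_finish < stop_finish
    if not escapes:
        return StopResponse(False, None, None, Outcome.STOP_INHIBITED)
    key = _choose_key(stimulus, params, rng)
    outcome = (
        Outcome.STOP_FAILED_CORRECT_KEY
        if key is stimulus
        else Outcome.STOP_FAILED_INCORRECT_KEY
    )
    return StopResponse(True, float(go_finish), key, outcome)


def apply_clock(
    ssd_programmed: float, clock: ClockModel, rng: np.random.Generator
) -> float:
    """Perturb a programmed SSD into the real-time-clock measured value."""
    if ssd_programmed < 0:
        raise ValueError("ssd_programmed must be non-negative")
    meta = ssd_programmed + rng.normal(clock.offset_mean, clock.offset_sd)
    if clock.quantum > 0:
        meta = round(meta / clock.quantum) * clock.quantum
    return float(max(meta, 0.0))


@dataclass(frozen=True)
class CohortMember:
    """One simulated participant: order arm plus per-session racer params."""

    participant_id: str
    order: str  # "independent_first" | "lab_first"
    lab: ParticipantParams
    independent: ParticipantParams

    def params_for(self, condition: str) -> ParticipantParams:
        if condition == "lab":
            return self.lab
        if condition == "independent":
            return self.independent
        raise ValueError(f"unknown condition {condition!r}")


def _truncated_normal(
    dist, rng: np.random.Generator, low: float = 0.0, high: float = np.inf
) -> float:
    """Normal(mean, sd) draw clipped into [low, high]."""
    return float(np.clip(rng.normal(dist.mean, dist.sd), low, high))


def sample_cohort(cohort: CohortParams, seed: Optional[int] = None) -> list[CohortMember]:
    """Draw a cohort of participants for a two-condition study.

    The latent stop latency of the two sessions is bivariate normal with
    the configured ``session_correlation``; all other parameters are
    drawn once per participant and shared across sessions.  Condition
    effects (stop-latency shift, choice-error increment) apply to the
    independent session.  Counterbalanced order alternates participants
    between the two arms.
    """
    rng = np.random.default_rng(seed)
    rho = cohort.session_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]]) * cohort.stop_mu.sd**2
    members: list[CohortMember] = []
    for i in range(cohort.n_participants):
        stop_pair = rng.multivariate_normal(
            [cohort.stop_mu.mean, cohort.stop_mu.mean], cov
        )
        stop_lab, stop_ind = np.maximum(stop_pair, 1.0)
        stop_ind += cohort.condition_effect_ssrt
        common = dict(
            go_mu=_truncated_normal(cohort.go_mu, rng, low=1.0),
            go_sigma=_truncated_normal(cohort.go_sigma, rng),
            go_tau=_truncated_normal(cohort.go_tau, rng),
            stop_sigma=_truncated_normal(cohort.stop_sigma, rng),
            p_trigger_failure=_truncated_normal(cohort.p_trigger_failure, rng, high=1.0),
            p_go_omission=_truncated_normal(cohort.p_go_omission, rng, high=1.0),
        )
        p_err = _truncated_normal(cohort.p_choice_error, rng, high=1.0)
        lab = ParticipantParams(stop_mu=stop_lab, p_choice_error=p_err, **common)
        ind = ParticipantParams(
            stop_mu=stop_ind,
            p_choice_error=float(np.clip(p_err + cohort.condition_effect_go_error, 0, 1)),
            **common,
        )
        if lab.mean_go_rt >= 1000.0:
            warnings.warn(
                f"participant {i}: mean go RT {lab.mean_go_rt:.0f} ms reaches the "
                "response window; expect heavy omissions",
                stacklevel=2,
            )
        if cohort.order is Order.COUNTERBALANCED:
            order = "independent_first" if i % 2 == 0 else "lab_first"
        else:
            order = cohort.order.value
        members.append(
            CohortMember(
                participant_id=f"p{i:04d}", order=order, lab=lab, independent=ind
            )
        )
    return members


_PARAM_FIELDS = list(ParticipantParams.model_fields)


def cohort_to_frame(members: Sequence[CohortMember]) -> pd.DataFrame:
    """Flatten a cohort to one row per participant-session for audit/CSV."""
    rows = []
    for m in members:
        for condition in ("lab", "independent"):
            p = m.params_for(condition)
            rows.append(
                {
                    "participant_id": m.participant_id,
                    "condition": condition,
                    "order": m.order,
                    **{f: getattr(p, f) for f in _PARAM_FIELDS},
                }
            )
    return pd.DataFrame(rows)


def frame_to_cohort(frame: pd.DataFrame) -> list[CohortMember]:
    """Inverse of :func:`cohort_to_frame`."""
    members = []
    for pid, grp in frame.groupby("participant_id", sort=False):
        by_cond = {
            row["condition"]: ParticipantParams(
                **{f: row[f] for f in _PARAM_FIELDS}
            )
            for _, row in grp.iterrows()
        }
        missing = {"lab", "independent"} - set(by_cond)
        if missing:
            raise ValueError(f"participant {pid}: missing condition(s) {missing}")
        members.append(
            CohortMember(
                participant_id=str(pid),
                order=str(grp["order"].iloc[0]),
                lab=by_cond["lab"],
                independent=by_cond["independent"],
            )
        )
    return members
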