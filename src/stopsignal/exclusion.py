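"""Participant-level exclusion rules.

A session is excluded when the race-model assumptions or task
compliance are in doubt: failed-stop RTs slower than the go RT mean
(race violation), stop accuracy outside 25-75% (staircase failed to
converge), go errors above 10%, or SSRT below 50 ms.  All inequalities
are strict; boundary values retain.  Study-level filtering then keeps
only participants with two clean sessions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .scoring import SessionMetrics

__all__ = ["ExclusionReason", "ExclusionReport", "apply_exclusion", "pair_filter"]


class ExclusionReason(str, enum.Enum):
    RACE_VIOLATION_CORRECT_KEY = "race_violation_correct_key"
    RACE_VIOLATION_INCORRECT_KEY = "race_violation_incorrect_key"
    STOP_ACCURACY_LOW = "stop_accuracy_low"
    STOP_ACCURACY_HIGH = "stop_accuracy_high"
    GO_ERRORS_HIGH = "go_errors_high"
    SSRT_LOW = "ssrt_low"
    INCOMPLETE_PAIR = "incomplete_pair"


@dataclass(frozen=True)
class ExclusionReport:
    session_id: str
    excluded: bool
    reasons: frozenset[ExclusionReason]

    def __post_init__(self) -> None:
        if self.excluded != bool(self.reasons):
            raise ValueError("excluded must hold iff reasons is nonempty")


def apply_exclusion(
    metrics: SessionMetrics, session_id: str = ""
) -> ExclusionReport:
    """Evaluate the session-level exclusion rules.

    Each rule is an independent predicate; a failed-stop RT stratum that
    is absent (no such trials) skips its race rule rather than firing.
    """
    reasons = set()
    if (
        metrics.failed_stop_correct_key_rt_mean is not None
        and metrics.failed_stop_correct_key_rt_mean > metrics.go_rt_mean
    ):
        reasons.add(ExclusionReason.RACE_VIOLATION_CORRECT_KEY)
    if (
        metrics.failed_stop_incorrect_key_rt_mean is not None
        and metrics.failed_stop_incorrect_key_rt_mean > metrics.go_rt_mean
    ):
        reasons.add(ExclusionReason.RACE_VIOLATION_INCORRECT_KEY)
    if metrics.stop_accuracy < 25.0:
        reasons.add(ExclusionReason.STOP_ACCURACY_LOW)
    if metrics.stop_accuracy > 75.0:
        reasons.add(ExclusionReason.STOP_ACCURACY_HIGH)
    if metrics.go_errors > 10.0:
        reasons.add(ExclusionReason.GO_ERRORS_HIGH)
    if metrics.ssrt < 50.0:
        reasons.add(ExclusionReason.SSRT_LOW)
    return ExclusionReport(
        session_id=session_id, excluded=bool(reasons), reasons=frozenset(reasons)
    )


def pair_filter(
    reports: Iterable[tuple[str, str, Optional[ExclusionReport]]],
) -> tuple[set[str], dict[str, set[ExclusionReason]]]:
    """Study-level filter over (participant_id, condition, report) rows.

    A participant is retained iff both conditions are present and
    neither session is excluded.  Returns the retained participant ids
    and, per dropped participant, the union of reasons (with
    ``incomplete_pair`` when a session is missing).  Duplicate
    (participant, condition) rows are rejected.
    """
    sessions: dict[str, dict[str, Optional[ExclusionReport]]] = {}
    for pid, condition, report in reports:
        by_cond = sessions.setdefault(pid, {})
        if condition in by_cond:
            raise ValueError(f"duplicate session for ({pid!r}, {condition!r})")
        by_cond[condition] = report

    retained: set[str] = set()
    dropped: dict[str, set[ExclusionReason]] = {}
    for pid, by_cond in sessions.items():
        reasons: set[ExclusionReason] = set()
        present = {c for c, r in by_cond.items() if r is not None}
        if present != {"lab", "independent"}:
            reasons.add(ExclusionReason.INCOMPLETE_PAIR)
        for report in by_cond.values():
            if report is not None:
                reasons |= set(report.reasons)
        if reasons:
            dropped[pid] = reasons
        else:
            retained.add(pid)
    return retained, dropped
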