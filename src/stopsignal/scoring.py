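"""Session scoring: the full per-session variable battery.

All metrics are computed over experimental trials only (practice is
excluded).  Percentages are of the relevant trial stratum: go accuracy,
omissions and errors are percent of go trials and sum to 100; stop
accuracy is percent of stop trials.  SSRT uses the mean method — mean
go RT minus mean stop-signal delay — with the clock-measured (meta)
delay by default.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from .config import ScoringOptions
from .types import Block, Outcome, TrialResult, TrialType

__all__ = ["SessionMetrics", "ScoringError", "score_session", "compute_ssrt"]


class ScoringError(ValueError):
    """Raised when a log lacks a stratum needed for scoring."""


@dataclass(frozen=True)
class SessionMetrics:
    """The per-session variable battery.

    RT means that have no qualifying trials (e.g. no incorrect-key
    failed stops) are ``None`` rather than 0.
    """

    go_accuracy: float          # % of go trials
    go_omissions: float         # % of go trials
    go_errors: float            # % of go trials
    go_rt_mean: float           # ms, correct go responses (by default)
    go_error_rt_mean: Optional[float]   # ms, wrong-key go responses
    intraindividual_sd: float   # ms, sample SD of correct-go RTs
    stop_accuracy: float        # % of stop trials successfully inhibited
    ssd_programmed_mean: float  # ms
    ssd_meta_mean: float        # ms
    failed_stop_correct_key_rt_mean: Optional[float]
    failed_stop_incorrect_key_rt_mean: Optional[float]
    ssrt: float                 # ms, mean method
    n_go: int
    n_stop: int

    def as_dict(self) -> dict:
        return asdict(self)


def compute_ssrt(go_rt_mean: float, ssd_mean: float) -> float:
    """Mean-method SSRT: mean go RT minus mean stop-signal delay.

    May be negative on degenerate sessions; the exclusion rules handle
    that downstream (SSRT < 50 ms excludes the session).
    """
    if not (np.isfinite(go_rt_mean) and np.isfinite(ssd_mean)):
        raise ValueError("go_rt_mean and ssd_mean must be finite")
    return float(go_rt_mean - ssd_mean)


def _mean(values: Sequence[float]) -> Optional[float]:
    return float(np.mean(values)) if values else None


def score_session(
    results: Sequence[TrialResult], options: Optional[ScoringOptions] = None
) -> SessionMetrics:
    """Score one session log into its variable battery.

    Practice trials are dropped first.  The main go-RT mean (and the
    intraindividual SD) use correct go responses; wrong-key go RTs are
    reported separately unless ``include_go_errors_in_rt`` folds them
    into the main mean.  Omissions contribute no RT anywhere.  Failed
    stop RTs are split by whether the pressed key matched the stimulus.
    """
    options = options or ScoringOptions()
    exp = [r for r in results if r.spec.block is not Block.PRACTICE]
    go = [r for r in exp if r.spec.trial_type is TrialType.GO]
    stop = [r for r in exp if r.spec.trial_type is TrialType.STOP]
    if not go:
        raise ScoringError("log has no experimental go trials")
    if not stop:
        raise ScoringError("log has no experimental stop trials")

    n_go, n_stop = len(go), len(stop)
    correct_rts = [r.rt for r in go if r.outcome is Outcome.GO_CORRECT]
    error_rts = [r.rt for r in go if r.outcome is Outcome.GO_ERROR]
    n_omit = sum(r.outcome is Outcome.GO_OMISSION for r in go)

    main_rts = correct_rts + error_rts if options.include_go_errors_in_rt else correct_rts
    if not main_rts:
        raise ScoringError("log has no scoreable go responses")
    go_rt_mean = float(np.mean(main_rts))
    # sample SD (n-1); a single RT gives zero variability by convention
    iisd = float(np.std(main_rts, ddof=1)) if len(main_rts) > 1 else 0.0

    inhibited = sum(r.outcome is Outcome.STOP_INHIBITED for r in stop)
    fs_correct = [r.rt for r in stop if r.outcome is Outcome.STOP_FAILED_CORRECT_KEY]
    fs_incorrect = [r.rt for r in stop if r.outcome is Outcome.STOP_FAILED_INCORRECT_KEY]
    ssd_prog = float(np.mean([r.ssd_programmed for r in stop]))
    ssd_meta = float(np.mean([r.ssd_meta for r in stop]))

    ssd_for_ssrt = ssd_meta if options.ssd_source == "meta" else ssd_prog
    return SessionMetrics(
        go_accuracy=100.0 * len(correct_rts) / n_go,
        go_omissions=100.0 * n_omit / n_go,
        go_errors=100.0 * len(error_rts) / n_go,
        go_rt_mean=go_rt_mean,
        go_error_rt_mean=_mean(error_rts),
        intraindividual_sd=iisd,
        stop_accuracy=100.0 * inhibited / n_stop,
        ssd_programmed_mean=ssd_prog,
        ssd_meta_mean=ssd_meta,
        failed_stop_correct_key_rt_mean=_mean(fs_correct),
        failed_stop_incorrect_key_rt_mean=_mean(fs_incorrect),
        ssrt=compute_ssrt(go_rt_mean, ssd_for_ssrt),
        n_go=n_go,
        n_stop=n_stop,
    )
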