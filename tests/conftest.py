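"""Shared fixtures and trial-log builders."""

from __future__ import annotations

import pytest

from stopsignal import SessionConfig
from stopsignal.scoring import SessionMetrics
from stopsignal.types import Block, Outcome, Stimulus, TrialResult, TrialSpec, TrialType

_counter = 0


def _next_index() -> int:
    global _counter
    _counter += 1
    return _counter


def go_trial(
    outcome: Outcome,
    rt: float | None = None,
    block: Block = Block.EXP1,
    stimulus: Stimulus = Stimulus.X,
    index: int | None = None,
) -> TrialResult:
    spec = TrialSpec(
        index=_next_index() if index is None else index,
        block=block,
        trial_type=TrialType.GO,
        go_stimulus=stimulus,
    )
    if outcome is Outcome.GO_OMISSION:
        return TrialResult(spec=spec, responded=False, outcome=outcome)
    key = stimulus if outcome is Outcome.GO_CORRECT else (
        Stimulus.O if stimulus is Stimulus.X else Stimulus.X
    )
    return TrialResult(spec=spec, responded=True, outcome=outcome, rt=rt, response_key=key)


def stop_trial(
    outcome: Outcome,
    ssd: float = 250.0,
    rt: float | None = None,
    block: Block = Block.EXP1,
    stimulus: Stimulus = Stimulus.X,
    ssd_meta: float | None = None,
    index: int | None = None,
) -> TrialResult:
    spec = TrialSpec(
        index=_next_index() if index is None else index,
        block=block,
        trial_type=TrialType.STOP,
        go_stimulus=stimulus,
    )
    meta = ssd if ssd_meta is None else ssd_meta
    if outcome is Outcome.STOP_INHIBITED:
        return TrialResult(
            spec=spec, responded=False, outcome=outcome, ssd_programmed=ssd, ssd_meta=meta
        )
    key = stimulus if outcome is Outcome.STOP_FAILED_CORRECT_KEY else (
        Stimulus.O if stimulus is Stimulus.X else Stimulus.X
    )
    return TrialResult(
        spec=spec,
        responded=True,
        outcome=outcome,
        rt=rt,
        response_key=key,
        ssd_programmed=ssd,
        ssd_meta=meta,
    )


def make_metrics(**overrides) -> SessionMetrics:
    """A clean SessionMetrics that passes every exclusion rule."""
    base = dict(
        go_accuracy=97.0,
        go_omissions=1.0,
        go_errors=2.0,
        go_rt_mean=490.0,
        go_error_rt_mean=430.0,
        intraindividual_sd=83.0,
        stop_accuracy=50.0,
        ssd_programmed_mean=250.0,
        ssd_meta_mean=251.0,
        failed_stop_correct_key_rt_mean=450.0,
        failed_stop_incorrect_key_rt_mean=380.0,
        ssrt=239.0,
        n_go=144,
        n_stop=48,
    )
    base.update(overrides)
    return SessionMetrics(**base)


@pytest.fixture
def default_config() -> SessionConfig:
    return SessionConfig()


@pytest.fixture
def eight_trial_log() -> list[TrialResult]:
    """The hand-enumerable 8-trial session used in scoring tests."""
    return [
        go_trial(Outcome.GO_CORRECT, rt=400.0),
        go_trial(Outcome.GO_CORRECT, rt=420.0),
        go_trial(Outcome.GO_CORRECT, rt=440.0),
        go_trial(Outcome.GO_CORRECT, rt=460.0),
        go_trial(Outcome.GO_ERROR, rt=300.0),
        go_trial(Outcome.GO_OMISSION),
        stop_trial(Outcome.STOP_INHIBITED, ssd=250.0),
        stop_trial(Outcome.STOP_FAILED_CORRECT_KEY, ssd=250.0, rt=350.0),
    ]
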