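"""Trial scheduling, the adaptive SSD staircase, session orchestration
and feedback generation.

``generate_schedule`` builds a constrained random trial order (exact
per-block stop counts, no two consecutive stop trials), ``run_session``
drives a simulated participant through it while the 1-up/1-down
staircase tracks the stop-signal delay, and ``feedback_events``
reconstructs the messages the task would have displayed.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .config import ConfigurationError, SessionConfig, ClockModel
from .participants import apply_clock, sample_go_response, sample_stop_outcome
from .config import ParticipantParams
from .types import (
    Block,
    Color,
    FeedbackEvent,
    MessageId,
    Outcome,
    StaircaseState,
    Stimulus,
    TrialResult,
    TrialSpec,
    TrialType,
)

__all__ = [
    "generate_schedule",
    "update_ssd",
    "run_session",
    "feedback_events",
]

def _block_types(
    n: int,
    n_stop: int,
    rng: np.random.Generator,
    forbid_first: bool,
) -> list[TrialType]:
    """Random order of n trials with exactly n_stop stops, none adjacent.

    Uniform over all valid arrangements: k non-consecutive positions out
    of m are in bijection with k-subsets of m-k+1 slots (shift the i-th
    chosen slot right by i).  ``forbid_first`` additionally bans a stop
    in position 0 (used when the previous block ended with one and the
    adjacency rule spans blocks), which just shrinks the position range
    by one.
    """
    offset = 1 if forbid_first else 0
    m = n - offset  # positions available to stop trials
    max_stops = (m + 1) // 2
    if n_stop > max_stops:
        raise ConfigurationError(
            f"cannot place {n_stop} non-consecutive stop trials in a "
            f"{n}-trial block (max {max_stops}); lower stop_fraction"
        )
    types = [TrialType.GO] * n
    if n_stop:
        slots = rng.choice(m - n_stop + 1, size=n_stop, replace=False)
        positions = np.sort(slots) + np.arange(n_stop) + offset
        for pos in positions:
            types[int(pos)] = TrialType.STOP
    return types


def generate_schedule(
    config: SessionConfig, seed: Optional[int] = None
) -> list[TrialSpec]:
    """Generate the full session trial order.

    Practice block first, then the experimental blocks.  Each block has
    exactly ``stop_fraction`` stop trials, stop trials are never
    consecutive within a block (and across block boundaries if
    ``stops_span_blocks``), and the go stimulus is drawn independently
    and uniformly from {X, O}.  Identical seeds give identical
    schedules.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    blocks: list[tuple[Block, int]] = []
    if config.n_practice_trials:
        blocks.append((Block.PRACTICE, config.n_practice_trials))
    for b in range(1, config.n_experimental_blocks + 1):
        blocks.append((Block.experimental(b), config.trials_per_block))

    schedule: list[TrialSpec] = []
    index = 0
    prev_was_stop = False
    for block, n in blocks:
        n_stop = round(config.stop_fraction * n)
        types = _block_types(
            n, n_stop, rng, forbid_first=config.stops_span_blocks and prev_was_stop
        )
        for t in types:
            stimulus = Stimulus.X if rng.random() < 0.5 else Stimulus.O
            schedule.append(
                TrialSpec(index=index, block=block, trial_type=t, go_stimulus=stimulus)
            )
            index += 1
        prev_was_stop = types[-1] is TrialType.STOP
    return schedule


def update_ssd(state: StaircaseState, inhibited: bool) -> StaircaseState:
    """Advance the staircase after one stop trial.

    Successful inhibition raises the SSD one step (stopping gets
    harder); a failed stop lowers it, clamped to [floor, ceiling].
    """
    return state.updated(inhibited)


def run_session(
    schedule: Sequence[TrialSpec],
    participant: ParticipantParams,
    config: SessionConfig,
    clock: Optional[ClockModel] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[TrialResult]:
    """Drive a simulated participant through a schedule.

    The staircase advances only on stop trials, using the outcome of the
    race at the clock-measured (meta) delay — the delay at which the stop
    signal actually appeared.  Both the programmed and meta SSD are
    recorded per stop trial.  By default the staircase resets to
    ``initial_ssd`` when experimental block 1 starts, so practice does
    not carry over (``carry_practice_ssd`` reverses this).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    clock = clock or ClockModel()
    staircase = StaircaseState(
        current_ssd=config.initial_ssd,
        step=config.ssd_step,
        floor=config.ssd_floor,
        ceiling=config.ssd_ceiling,
    )
    window = config.stimulus_duration
    results: list[TrialResult] = []
    in_practice = None
    for spec in schedule:
        is_practice = spec.block is Block.PRACTICE
        if in_practice and not is_practice and not config.carry_practice_ssd:
            staircase = StaircaseState(
                current_ssd=config.initial_ssd,
                step=config.ssd_step,
                floor=config.ssd_floor,
                ceiling=config.ssd_ceiling,
            )
        in_practice = is_practice

        if spec.trial_type is TrialType.GO:
            go = sample_go_response(participant, spec.go_stimulus, rng, window)
            results.append(
                TrialResult(
                    spec=spec,
                    responded=go.responded,
                    outcome=go.outcome,
                    rt=go.rt,
                    response_key=go.response_key,
                )
            )
        else:
            ssd_prog = staircase.current_ssd
            ssd_meta = apply_clock(ssd_prog, clock, rng)
            stop = sample_stop_outcome(
                participant, ssd_meta, spec.go_stimulus, rng, window
            )
            results.append(
                TrialResult(
                    spec=spec,
                    responded=stop.responded,
                    outcome=stop.outcome,
                    rt=stop.rt,
                    response_key=stop.response_key,
                    ssd_programmed=ssd_prog,
                    ssd_meta=ssd_meta,
                )
            )
            staircase = update_ssd(staircase, not stop.responded)
    return results


_PRACTICE_OUTCOME_FEEDBACK = {
    Outcome.GO_OMISSION: (MessageId.MISS_OMISSION, Color.RED),
    Outcome.GO_ERROR: (MessageId.MISS_INCORRECT, Color.RED),
    Outcome.STOP_INHIBITED: (MessageId.STOP_SUCCESS, Color.GREEN),
    Outcome.STOP_FAILED_CORRECT_KEY: (MessageId.STOP_FAIL, Color.RED),
    Outcome.STOP_FAILED_INCORRECT_KEY: (MessageId.STOP_FAIL, Color.RED),
}


def feedback_events(
    results: Sequence[TrialResult], config: SessionConfig
) -> list[FeedbackEvent]:
    """Reconstruct the feedback stream for a completed session.

    Practice trials each emit one outcome message (Hit / Hit-but-faster /
    Miss variants / stop success or failure); every third consecutive go
    omission triggers a red warning in any block; and each block closes
    with the five summary items (go errors, go misses, mean go RT with a
    "too slow" variant at ≥ ``slow_rt_threshold``, stop accuracy %, and
    the 10-second countdown).
    """
    events: list[FeedbackEvent] = []
    consecutive_omissions = 0
    block_results: list[TrialResult] = []
    current_block: Optional[Block] = None

    def close_block(block: Block, trials: list[TrialResult]) -> None:
        go = [r for r in trials if r.spec.trial_type is TrialType.GO]
        stop = [r for r in trials if r.spec.trial_type is TrialType.STOP]
        go_rts = [r.rt for r in go if r.rt is not None]
        mean_rt = float(np.mean(go_rts)) if go_rts else None
        too_slow = mean_rt is not None and mean_rt >= config.slow_rt_threshold
        idx = trials[-1].spec.index
        events.append(
            FeedbackEvent(
                idx,
                MessageId.SUMMARY_GO_ERRORS,
                Color.WHITE,
                {"block": block.value, "n": sum(r.outcome is Outcome.GO_ERROR for r in go)},
            )
        )
        events.append(
            FeedbackEvent(
                idx,
                MessageId.SUMMARY_GO_MISSES,
                Color.WHITE,
                {"block": block.value, "n": sum(r.outcome is Outcome.GO_OMISSION for r in go)},
            )
        )
        events.append(
            FeedbackEvent(
                idx,
                MessageId.SUMMARY_MEAN_RT,
                Color.RED if too_slow else Color.WHITE,
                {"block": block.value, "mean_rt": mean_rt, "too_slow": too_slow},
            )
        )
        stop_pct = (
            100.0 * sum(r.outcome is Outcome.STOP_INHIBITED for r in stop) / len(stop)
            if stop
            else None
        )
        events.append(
            FeedbackEvent(
                idx,
                MessageId.SUMMARY_STOP_PCT,
                Color.WHITE,
                {"block": block.value, "stop_pct": stop_pct},
            )
        )
        events.append(
            FeedbackEvent(
                idx,
                MessageId.SUMMARY_COUNTDOWN,
                Color.WHITE,
                {"block": block.value, "seconds": 10},
            )
        )

    for r in results:
        if current_block is not None and r.spec.block is not current_block:
            close_block(current_block, block_results)
            block_results = []
            consecutive_omissions = 0
        current_block = r.spec.block
        block_results.append(r)

        if r.spec.block is Block.PRACTICE:
            if r.outcome is Outcome.GO_CORRECT:
                assert r.rt is not None
                if r.rt < config.slow_rt_threshold:
                    events.append(
                        FeedbackEvent(r.spec.index, MessageId.HIT, Color.GREEN)
                    )
                else:
                    events.append(
                        FeedbackEvent(r.spec.index, MessageId.HIT_TOO_SLOW, Color.YELLOW)
                    )
            else:
                mid, color = _PRACTICE_OUTCOME_FEEDBACK[r.outcome]
                events.append(FeedbackEvent(r.spec.index, mid, color))

        if r.outcome is Outcome.GO_OMISSION:
            consecutive_omissions += 1
            if consecutive_omissions % config.consecutive_omission_warning == 0:
                events.append(
                    FeedbackEvent(
                        r.spec.index,
                        MessageId.OMISSION_WARNING,
                        Color.RED,
                        {"count": consecutive_omissions},
                    )
                )
        elif r.spec.trial_type is TrialType.GO:
            consecutive_omissions = 0

    if current_block is not None and block_results:
        close_block(current_block, block_results)
    return events
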