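"""Trial-log and metrics I/O plus the end-to-end study runner.

Trial logs are plain CSV, one row per trial, human-auditable (a session
is at most a few hundred rows).  ``read_trial_log`` validates every row
against the cross-field rules the trial structure implies (RT present
iff responded, SSD fields only on stop trials, key accord consistent
with the outcome) and reports offending line numbers.

``run_study`` ties the pipeline together: cohort sampling → per-session
simulation → scoring → exclusion → analysis, with every random stream
derived from one master seed via counter-based spawn keys so that
adding participants never perturbs earlier streams.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import ScoringOptions, StudyConfig
from .exclusion import apply_exclusion, pair_filter
from .participants import CohortMember, cohort_to_frame, sample_cohort
from .scoring import score_session
from .stats import analyze_study
from .task import generate_schedule, run_session
from .types import Block, Outcome, Stimulus, TrialResult, TrialSpec, TrialType

__all__ = [
    "LogValidationError",
    "write_trial_log",
    "read_trial_log",
    "write_metrics",
    "read_metrics",
    "run_study",
]

LOG_COLUMNS = [
    "session_id",
    "condition",
    "trial_index",
    "block",
    "trial_type",
    "go_stimulus",
    "ssd_programmed_ms",
    "ssd_meta_ms",
    "responded",
    "response_key",
    "rt_ms",
    "outcome",
]


class LogValidationError(ValueError):
    """Raised when a trial log fails schema or cross-field validation."""

    def __init__(self, path, problems: list[str]):
        self.problems = problems
        shown = "\n  ".join(problems[:20])
        more = f"\n  ... and {len(problems) - 20} more" if len(problems) > 20 else ""
        super().__init__(f"{path}: {len(problems)} invalid row(s):\n  {shown}{more}")


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_trial_log(
    path, results: Sequence[TrialResult], session_id: str, condition: str
) -> None:
    """Write one session's trial log as CSV (absent fields empty)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(LOG_COLUMNS)
        for r in results:
            w.writerow(
                [
                    session_id,
                    condition,
                    r.spec.index,
                    r.spec.block.value,
                    r.spec.trial_type.value,
                    r.spec.go_stimulus.value,
                    _fmt(r.ssd_programmed),
                    _fmt(r.ssd_meta),
                    _fmt(r.responded),
                    _fmt(r.response_key.value if r.response_key else None),
                    _fmt(r.rt),
                    r.outcome.value,
                ]
            )


def _parse_row(row: dict, lineno: int, problems: list[str]) -> Optional[TrialResult]:
    def fail(msg: str) -> None:
        problems.append(f"line {lineno}: {msg}")

    try:
        spec = TrialSpec(
            index=int(row["trial_index"]),
            block=Block(row["block"]),
            trial_type=TrialType(row["trial_type"]),
            go_stimulus=Stimulus(row["go_stimulus"]),
        )
        responded = {"true": True, "false": False}[row["responded"].lower()]
        rt = float(row["rt_ms"]) if row["rt_ms"] != "" else None
        key = Stimulus(row["response_key"]) if row["response_key"] != "" else None
        ssd_p = float(row["ssd_programmed_ms"]) if row["ssd_programmed_ms"] != "" else None
        ssd_m = float(row["ssd_meta_ms"]) if row["ssd_meta_ms"] != "" else None
        outcome = Outcome(row["outcome"])
    except (KeyError, ValueError) as e:
        fail(f"unparseable field ({e})")
        return None
    try:
        # TrialResult enforces the cross-field invariants on construction
        return TrialResult(
            spec=spec,
            responded=responded,
            outcome=outcome,
            rt=rt,
            response_key=key,
            ssd_programmed=ssd_p,
            ssd_meta=ssd_m,
        )
    except ValueError as e:
        fail(str(e))
        return None


def read_trial_log(path) -> tuple[list[TrialResult], str, str]:
    """Read and validate a trial log; returns (results, session_id, condition)."""
    problems: list[str] = []
    results: list[TrialResult] = []
    session_id = condition = ""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(LOG_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise LogValidationError(path, [f"missing column(s): {sorted(missing)}"])
        for lineno, row in enumerate(reader, start=2):
            parsed = _parse_row(row, lineno, problems)
            if parsed is not None:
                results.append(parsed)
                session_id = row["session_id"]
                condition = row["condition"]
    if problems:
        raise LogValidationError(path, problems)
    return results, session_id, condition


def write_metrics(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path)


def session_seed(master_seed: int, participant_index: int, session_index: int) -> np.random.Generator:
    """Counter-based per-session stream: SeedSequence(master, key=(p, s))."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(participant_index, session_index))
    )


@dataclass
class StudyResult:
    """In-memory product of one simulated study."""

    metrics: pd.DataFrame
    exclusions: pd.DataFrame
    retained: set[str]
    report: object
    manifest: dict


def simulate_session(
    member: CohortMember,
    condition: str,
    config: StudyConfig,
    participant_index: int,
    session_index: int,
) -> list[TrialResult]:
    rng = session_seed(config.master_seed, participant_index, session_index)
    schedule = generate_schedule(config.session, seed=int(rng.integers(2**31)))
    return run_session(
        schedule,
        member.params_for(condition),
        config.session,
        clock=config.clock,
        rng=rng,
    )


def run_study(
    config: StudyConfig, out_dir: Optional[str | Path] = None, write_logs: bool = True
) -> StudyResult:
    """Simulate, score, exclude and analyze a complete two-session study.

    When ``out_dir`` is given, writes trial logs, ``metrics.csv``,
    ``exclusions.csv``, ``analysis.json``, ``cohort.csv`` and a
    ``manifest.json`` recording seeds and the participant funnel
    (recruited → completed both sessions → retained after exclusion).
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        if write_logs:
            (out / "logs").mkdir(exist_ok=True)

    members = sample_cohort(
        config.cohort,
        seed=np.random.SeedSequence(config.master_seed, spawn_key=(2**31,)),
    )
    rows = []
    reports = []
    for i, member in enumerate(members):
        # session order is chronological; condition per the order arm
        conditions = (
            ("independent", "lab")
            if member.order == "independent_first"
            else ("lab", "independent")
        )
        for s, condition in enumerate(conditions):
            results = simulate_session(member, condition, config, i, s)
            session_id = f"{member.participant_id}_{condition}"
            if out is not None and write_logs:
                write_trial_log(
                    out / "logs" / f"{session_id}.csv", results, session_id, condition
                )
            metrics = score_session(results, config.scoring)
            rows.append(
                {
                    "participant_id": member.participant_id,
                    "condition": condition,
                    "order": member.order,
                    "session_id": session_id,
                    **metrics.as_dict(),
                }
            )
            reports.append(
                (
                    member.participant_id,
                    condition,
                    apply_exclusion(metrics, session_id),
                )
            )

    metrics_df = pd.DataFrame(rows)
    retained, dropped = pair_filter(reports)
    excl_rows = [
        {
            "session_id": rep.session_id,
            "participant_id": pid,
            "condition": cond,
            "excluded": rep.excluded,
            "reasons": ";".join(sorted(r.value for r in rep.reasons)),
        }
        for pid, cond, rep in reports
    ]
    excl_df = pd.DataFrame(excl_rows)
    report = analyze_study(metrics_df, retained)

    manifest = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "seed_derivation": "SeedSequence(master_seed, spawn_key=(participant_index, session_index))",
        "n_recruited": len(members),
        "n_completed_both": len(members),  # simulated participants always finish
        "n_retained": len(retained),
        "n_dropped": len(dropped),
        "dropped": {pid: sorted(r.value for r in rs) for pid, rs in sorted(dropped.items())},
        "trials_per_session": config.session.n_trials,
    }
    if out is not None:
        write_metrics(out / "metrics.csv", metrics_df)
        excl_df.to_csv(out / "exclusions.csv", index=False)
        cohort_to_frame(members).to_csv(out / "cohort.csv", index=False)
        (out / "analysis.json").write_text(json.dumps(report.as_dict(), indent=2))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return StudyResult(
        metrics=metrics_df,
        exclusions=excl_df,
        retained=retained,
        report=report,
        manifest=manifest,
    )
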