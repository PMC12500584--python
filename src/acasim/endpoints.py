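"""Baseline, tracked variables and analysis endpoints.

The rank and score of the last run-in run are the baseline. The variable
tracked through the evaluation phase is the score under the fixed-rank
paradigm and the rank under the adaptive-rank paradigm (scores across
different ranks are not comparable). Three endpoints are derived per
subject: change from baseline, percentage change from baseline, and the
time to confirmed decline — the first run at which the tracked value has
dropped by more than ``threshold_fraction`` below baseline and stays there
for at least ``confirm_runs`` consecutive runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .trajectory_engine import ADAPTIVE_RANK, FIXED_RANK, StudySpec, Trajectory

__all__ = [
    "EndpointRecord",
    "baseline_of",
    "tracked_series",
    "change_endpoints",
    "confirmed_decline",
    "derive_endpoint_records",
    "endpoint_table",
]


@dataclass(frozen=True)
class EndpointRecord:
    """Per-subject endpoint values and event/censoring information.

    ``event_run``/``censor_run`` count evaluation-phase runs since baseline
    (1 = first post-baseline run); exactly one of them is set.
    ``percent_change_from_baseline`` is None (undefined) when the baseline
    value is 0. ``structural_censor`` marks subjects whose tracked variable
    cannot decline past the threshold (e.g. baseline rank 1 under the
    adaptive paradigm).
    """

    subject_id: int
    baseline_rank: int
    baseline_score: float
    baseline_value: float
    value_at_study_end: float
    change_from_baseline: float
    percent_change_from_baseline: Optional[float]
    event_flag: bool
    event_run: Optional[int]
    censor_run: Optional[int]
    structural_censor: bool = False

    def __post_init__(self) -> None:
        if (self.event_run is None) == (self.censor_run is None):
            raise ValueError("exactly one of event_run / censor_run must be set")


def baseline_of(trajectory: Trajectory, study: StudySpec) -> tuple[int, float]:
    """(rank, score) at the last run of the run-in phase."""
    if study.run_in_runs == 0:
        raise ValueError("no baseline defined: run_in_runs is 0")
    if len(trajectory) < study.run_in_runs:
        raise ValueError(
            f"trajectory has {len(trajectory)} runs, need >= {study.run_in_runs}"
        )
    idx = study.run_in_runs - 1
    return int(trajectory.ranks[idx]), float(trajectory.scores[idx])


def tracked_series(
    trajectory: Trajectory, paradigm: str, run_in_runs: int = 14
) -> np.ndarray:
    """Evaluation-phase values of the tracked variable.

    Scores for the fixed-rank paradigm, ranks (as floats) for the
    adaptive-rank paradigm; one value per run after ``run_in_runs``.
    """
    if paradigm == FIXED_RANK:
        return trajectory.scores[run_in_runs:].astype(float)
    if paradigm == ADAPTIVE_RANK:
        return trajectory.ranks[run_in_runs:].astype(float)
    raise ValueError(f"unknown paradigm {paradigm!r}")


def change_endpoints(
    series: np.ndarray, baseline_value: float
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Change and percentage change from baseline at every run.

    The percentage series is None (flagged undefined) when the baseline is
    0; this is not an error.
    """
    series = np.asarray(series, dtype=float)
    change = series - baseline_value
    if baseline_value == 0:
        return change, None
    return change, 100.0 * change / baseline_value


def confirmed_decline(
    series: np.ndarray,
    baseline_value: float,
    threshold_fraction: float = 0.30,
    confirm_runs: int = 8,
) -> tuple[bool, int]:
    """First sustained drop of more than ``threshold_fraction`` below baseline.

    Returns ``(True, onset_run)`` for the first (1-based) position r such
    that the value is strictly below baseline * (1 - threshold_fraction) at
    r and at every one of the following ``confirm_runs - 1`` positions. A
    qualifying streak truncated by the end of the series does not confirm;
    then (and when no drop occurs) the result is ``(False, last_position)``.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("series must be nonempty")
    if baseline_value <= 0:
        raise ValueError(f"baseline must be > 0, got {baseline_value}")
    below = series < baseline_value * (1.0 - threshold_fraction)
    if series.size >= confirm_runs:
        # window[i] = all(below[i : i + confirm_runs])
        window = np.lib.stride_tricks.sliding_window_view(below, confirm_runs).all(
            axis=1
        )
        hits = np.flatnonzero(window)
        if hits.size:
            return True, int(hits[0]) + 1
    return False, int(series.size)


def derive_endpoint_records(
    trajectories: list[Trajectory],
    study: StudySpec,
    threshold_fraction: float = 0.30,
    confirm_runs: int = 8,
) -> list[EndpointRecord]:
    """Full endpoint derivation for every subject of a simulated cohort."""
    records = []
    for t in trajectories:
        b_rank, b_score = baseline_of(t, study)
        baseline = float(b_score) if study.paradigm == FIXED_RANK else float(b_rank)
        series = tracked_series(t, study.paradigm, study.run_in_runs)
        change, pct = change_endpoints(series, baseline)
        event, run = confirmed_decline(
            series, baseline, threshold_fraction, confirm_runs
        )
        # a tracked variable floored at its minimum possible value can never
        # cross the decline threshold: structurally censored
        if study.paradigm == ADAPTIVE_RANK:
            structural = 1.0 >= baseline * (1.0 - threshold_fraction)
        else:
            structural = False
        records.append(
            EndpointRecord(
                subject_id=t.subject_id,
                baseline_rank=b_rank,
                baseline_score=b_score,
                baseline_value=baseline,
                value_at_study_end=float(series[-1]),
                change_from_baseline=float(change[-1]),
                percent_change_from_baseline=(
                    None if pct is None else float(pct[-1])
                ),
                event_flag=event,
                event_run=run if event else None,
                censor_run=None if event else run,
                structural_censor=bool(structural and not event),
            )
        )
    return records


def endpoint_table(records: list[EndpointRecord], **labels) -> pd.DataFrame:
    """One row per subject; extra keyword labels become constant columns."""
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "baseline_rank": [r.baseline_rank for r in records],
            "baseline_score": [r.baseline_score for r in records],
            "baseline_value": [r.baseline_value for r in records],
            "value_at_study_end": [r.value_at_study_end for r in records],
            "change_from_baseline": [r.change_from_baseline for r in records],
            "percent_change_from_baseline": [
                np.nan if r.percent_change_from_baseline is None
                else r.percent_change_from_baseline
                for r in records
            ],
            "event": [r.event_flag for r in records],
            "time": [r.event_run if r.event_flag else r.censor_run for r in records],
            "structural_censor": [r.structural_censor for r in records],
        }
    )
    for k, v in labels.items():
        df[k] = v
    return df
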