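"""Iterative generation of subject trajectories and cohorts.

A trajectory is the ordered sequence of (rank, score) pairs over a
subject's runs. Each run draws a score from the subject model — from the
marginal distribution at the first run and after every rank change,
otherwise from the AR(1) conditional law — and then applies the study
model's transition rules to pick the next rank.

The study has two phases: a run-in of daily testing (default 14 runs) with
adaptation at every run, whose last run defines the baseline, and an
evaluation phase (weekly testing) in which difficulty is either frozen at
the baseline rank ("fixed_rank") or continues to adapt ("adaptive_rank").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .param_space import (
    ConfigError,
    DeclineParams,
    InstrumentSpec,
    LearningParams,
    SimulationConfig,
)
from .study_model import TransitionRules, default_cutoffs, next_rank
from .subject_model import (
    SubjectProfile,
    draw_score_conditional,
    draw_score_marginal,
    run_mean_sd,
)

__all__ = [
    "StudySpec",
    "CohortSpec",
    "Trajectory",
    "build_schedule",
    "simulate_subject",
    "simulate_cohort",
    "study_spec_from_config",
    "cohort_specs_from_config",
    "trajectories_to_frame",
]

FIXED_RANK = "fixed_rank"
ADAPTIVE_RANK = "adaptive_rank"


@dataclass(frozen=True)
class StudySpec:
    """Schedule and deployment paradigm for one simulated study arm."""

    run_in_runs: int = 14
    total_runs: int = 220
    paradigm: str = FIXED_RANK
    initial_rank: Optional[int] = None  # None -> middle rank
    rules_run_in: TransitionRules = None  # type: ignore[assignment]
    rules_evaluation: TransitionRules = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0 <= self.run_in_runs < self.total_runs:
            raise ConfigError(
                f"require 0 <= run_in_runs < total_runs, got "
                f"{self.run_in_runs}, {self.total_runs}"
            )
        if self.paradigm not in (FIXED_RANK, ADAPTIVE_RANK):
            raise ConfigError(f"unknown paradigm {self.paradigm!r}")

    def start_rank(self, spec: InstrumentSpec) -> int:
        if self.initial_rank is not None:
            if not 1 <= self.initial_rank <= spec.n_ranks:
                raise ConfigError(
                    f"initial_rank {self.initial_rank} outside [1, {spec.n_ranks}]"
                )
            return self.initial_rank
        return (spec.n_ranks + 1) // 2


@dataclass(frozen=True)
class CohortSpec:
    """A simulated cohort: size, subject-model parameters, instrument."""

    n_subjects: int
    decline: DeclineParams
    learning: LearningParams
    instrument: InstrumentSpec
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError(f"n_subjects must be >= 1, got {self.n_subjects}")


@dataclass
class Trajectory:
    """One subject's simulated run sequence.

    ``runs`` are contiguous 1-based indices; ``phase`` is "run_in" for runs
    up to the run-in length and "evaluation" after.
    """

    subject_id: int
    runs: np.ndarray
    ranks: np.ndarray
    scores: np.ndarray
    run_in_runs: int

    def __len__(self) -> int:
        return len(self.runs)

    @property
    def phase(self) -> np.ndarray:
        return np.where(self.runs <= self.run_in_runs, "run_in", "evaluation")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "run": self.runs,
                "phase": self.phase,
                "rank": self.ranks,
                "score": self.scores,
            }
        )


def build_schedule(
    years: float, run_in_days: int = 14, evaluation_interval_days: int = 7
) -> int:
    """Total number of runs for a daily run-in followed by spaced testing.

    The horizon is measured from study start and includes the run-in; one
    year is taken as 52 weeks (364 days). Daily testing for
    ``run_in_days``, then one run per ``evaluation_interval_days`` for the
    remainder: 4 years with a 14-day run-in and weekly testing gives
    14 + 206 = 220 runs.
    """
    if years <= 0 or run_in_days <= 0 or evaluation_interval_days <= 0:
        raise ValueError("all schedule arguments must be positive")
    horizon_days = int(round(years * 52 * 7))
    if horizon_days < run_in_days:
        raise ValueError(
            f"horizon ({horizon_days} d) shorter than the run-in ({run_in_days} d)"
        )
    return run_in_days + (horizon_days - run_in_days) // evaluation_interval_days


def simulate_subject(
    profile: SubjectProfile, study: StudySpec, rng: np.random.Generator
) -> Trajectory:
    """Generate one trajectory by alternating score draws and rank updates.

    The first run and every run directly after a rank change draw from the
    marginal normal at the current rank; other runs draw from the
    conditional law given the previous score. The rank of run k+1 is
    decided by the run-in rules while k+1 is still within the run-in, and
    by the evaluation regime (identity under fixed_rank) afterwards, so
    under fixed_rank the evaluation rank equals the baseline rank.
    """
    spec = profile.instrument
    n = study.total_runs
    ranks = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)

    rank = study.start_rank(spec)
    tail: list[tuple[int, float]] = []
    prev_mu = prev_sd = None

    for k in range(1, n + 1):
        first = profile.is_first_execution(rank)
        mu, sd = run_mean_sd(profile, rank, k, first)
        if not tail:  # run 1 or the rank has just changed
            score = draw_score_marginal(mu, sd, spec.bounds, rng)
        else:
            rho = spec.params_at(rank).rho
            score = draw_score_conditional(
                scores[k - 2], prev_mu, prev_sd, mu, sd, rho, spec.bounds, rng
            )
        ranks[k - 1] = rank
        scores[k - 1] = score
        profile.mark_visited(rank)
        tail.append((rank, score))
        prev_mu, prev_sd = mu, sd

        if k < n:
            if k + 1 <= study.run_in_runs:
                rules = study.rules_run_in
            elif study.paradigm == ADAPTIVE_RANK:
                rules = study.rules_evaluation
            else:
                rules = None  # fixed_rank: frozen at the baseline rank
            new_rank = (
                rank if rules is None else next_rank(rules, tail, rank, spec.n_ranks)
            )
            if new_rank != rank:
                tail = []
                rank = new_rank

    return Trajectory(
        subject_id=profile.subject_id,
        runs=np.arange(1, n + 1),
        ranks=ranks,
        scores=scores,
        run_in_runs=study.run_in_runs,
    )


def simulate_cohort(
    cohort: CohortSpec, study: StudySpec, seed: int
) -> list[Trajectory]:
    """Simulate all subjects of a cohort with independent RNG substreams.

    Substreams are spawned deterministically from ``seed`` and the subject
    index, so results are bit-reproducible and independent of execution
    order.
    """
    out = []
    for i in range(cohort.n_subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        )
        profile = SubjectProfile(
            subject_id=i + 1,
            learning=cohort.learning,
            decline=cohort.decline,
            instrument=cohort.instrument,
        )
        out.append(simulate_subject(profile, study, rng))
    return out


def study_spec_from_config(config: SimulationConfig, paradigm: str) -> StudySpec:
    """Build the StudySpec for one paradigm from a full configuration."""
    spec = config.instrument_spec
    return StudySpec(
        run_in_runs=config.run_in_runs,
        total_runs=config.total_runs,
        paradigm=paradigm,
        initial_rank=config.initial_rank,
        rules_run_in=default_cutoffs(
            spec,
            z_up=config.z_up,
            z_down=config.z_down,
            n_consec_up=config.n_consec_up_run_in,
            n_consec_down=config.n_consec_down_run_in,
        ),
        rules_evaluation=default_cutoffs(
            spec,
            z_up=config.z_up,
            z_down=config.z_down,
            n_consec_up=config.n_consec_up,
            n_consec_down=config.n_consec_down,
        ),
    )


def cohort_specs_from_config(config: SimulationConfig) -> list[CohortSpec]:
    """One cohort per decline rate in the configuration's grid."""
    return [
        CohortSpec(
            n_subjects=config.n_subjects,
            decline=DeclineParams(rate_per_run=rate, stable_runs=config.stable_runs),
            learning=config.learning,
            instrument=config.instrument_spec,
            label=f"decline_{rate:g}",
        )
        for rate in config.decline_rates
    ]


def trajectories_to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Long-format table: subject_id, run, phase, rank, score."""
    return pd.concat([t.to_frame() for t in trajectories], ignore_index=True)
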