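"""Probabilistic individual-subject score model.

A subject's score at each run is normally distributed with a rank-specific
mean and SD. Two deterministic multipliers act on the expectation only:

* a half-sigmoidal learning/practice multiplier L(run) rising from exactly
  1 at the first run toward the asymptote ``maximum``;
* a decline multiplier equal to 1 for an initial stable phase and falling
  linearly thereafter, floored at 0.

Within a stay at a given rank, consecutive scores follow a (generally
non-stationary) first-order autoregressive process realized through the
conditional law of a bivariate normal; after a rank change the chain
restarts from the marginal distribution at the new rank. Draws are clamped
post hoc to the instrument's score bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .param_space import DeclineParams, InstrumentSpec, LearningParams

__all__ = [
    "SubjectProfile",
    "learning_multiplier",
    "decline_multiplier",
    "run_mean_sd",
    "conditional_params",
    "draw_score_marginal",
    "draw_score_conditional",
]

Bounds = tuple[float, float | None]


def learning_multiplier(params: LearningParams, run):
    """Learning/practice-effect multiplier L at a 1-based run index.

    L(run) = maximum / (1 + (maximum - 1) * exp(-rate * (run - 1))), the
    half-sigmoid with L(1) = 1 exactly and L -> maximum as run grows. For
    maximum = 1 the multiplier is identically 1. Accepts scalar or array
    ``run``.
    """
    run = np.asarray(run)
    if np.any(run < 1):
        raise ValueError("run index must be >= 1")
    m, rate = params.maximum, params.rate
    if m == 1.0:
        out = np.ones_like(run, dtype=float)
    else:
        out = m / (1.0 + (m - 1.0) * np.exp(-rate * (run - 1)))
    return float(out) if out.ndim == 0 else out


def decline_multiplier(params: DeclineParams, run):
    """Cognitive-decline multiplier at a 1-based run index.

    1 for run <= stable_runs, then 1 - rate_per_run * (run - stable_runs),
    never below 0. Accepts scalar or array ``run``.
    """
    run = np.asarray(run)
    if np.any(run < 1):
        raise ValueError("run index must be >= 1")
    excess = np.maximum(run - params.stable_runs, 0)
    out = np.maximum(1.0 - params.rate_per_run * excess, 0.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class SubjectProfile:
    """Per-subject model parameters and first-execution bookkeeping.

    ``visited_ranks`` records every rank the subject has executed at least
    once; the set only grows during a simulation and selects between
    first- and second-execution distribution parameters.
    """

    subject_id: int
    learning: LearningParams
    decline: DeclineParams
    instrument: InstrumentSpec
    visited_ranks: set[int] = field(default_factory=set)

    def is_first_execution(self, rank: int) -> bool:
        return rank not in self.visited_ranks

    def mark_visited(self, rank: int) -> None:
        self.visited_ranks.add(rank)


def run_mean_sd(
    profile: SubjectProfile,
    rank: int,
    run: int,
    is_first_execution_at_rank: bool,
) -> tuple[float, float]:
    """Expectation and SD of the score at a given rank and global run.

    mu = (mu_first or mu_second) * L(run) * D(run); the multipliers act on
    the expectation only, so sigma is the stored first- or second-execution
    SD unchanged.
    """
    rp = profile.instrument.params_at(rank)
    mult = learning_multiplier(profile.learning, run) * decline_multiplier(
        profile.decline, run
    )
    if is_first_execution_at_rank:
        return rp.mu_first * mult, rp.sigma_first
    return rp.mu_second * mult, rp.sigma_second


def _clamp(score, bounds: Bounds):
    floor, ceiling = bounds
    score = np.maximum(score, floor)
    if ceiling is not None:
        score = np.minimum(score, ceiling)
    return score


def draw_score_marginal(mu, sigma, bounds: Bounds, rng: np.random.Generator, size=None):
    """One draw (or ``size`` draws) from N(mu, sigma^2), clamped to bounds.

    Used at the first run of a trajectory and whenever the rank has just
    changed. A score below the floor is set to the floor; on a
    ceiling-bounded instrument a score above the ceiling is set to the
    ceiling.
    """
    raw = rng.normal(mu, sigma, size=size)
    out = _clamp(raw, bounds)
    return float(out) if np.ndim(out) == 0 else out


def conditional_params(
    prev_score, mu_j, sigma_j, mu_next, sigma_next, rho
) -> tuple[float, float]:
    """Mean and SD of the next score given the previous one.

    From the bivariate normal of consecutive scores:
    mean = mu_next + rho * sigma_next * (prev - mu_j) / sigma_j,
    variance = (1 - rho^2) * sigma_next^2.
    """
    mean = mu_next + rho * sigma_next * (np.asarray(prev_score) - mu_j) / sigma_j
    sd = np.sqrt(max(1.0 - rho * rho, 0.0)) * sigma_next
    return mean, sd


def draw_score_conditional(
    prev_score,
    mu_j,
    sigma_j,
    mu_next,
    sigma_next,
    rho,
    bounds: Bounds,
    rng: np.random.Generator,
):
    """Draw the next score conditional on the previous one, then clamp.

    With rho = 0 this reduces to the marginal N(mu_next, sigma_next^2);
    with rho = 1 and equal parameters the next score equals the previous
    one. ``prev_score`` may be an array (one chain per element).
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [-1, 1], got {rho}")
    if sigma_j <= 0 or sigma_next <= 0:
        raise ValueError("sigmas must be > 0")
    mean, sd = conditional_params(prev_score, mu_j, sigma_j, mu_next, sigma_next, rho)
    raw = mean + sd * rng.standard_normal(size=np.shape(mean) or None)
    out = _clamp(raw, bounds)
    return float(out) if np.ndim(out) == 0 else out
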