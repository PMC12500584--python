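"""Deterministic rank-transition rules (the study model).

After each run, the study model maps the recent scores at the current rank
to the next rank: promotion to the next harder rank when the latest
``n_consec_up`` scores all exceed the rank's promotion cutoff, demotion
when the latest ``n_consec_down`` scores all fall below the demotion
cutoff, otherwise no change. Streaks are counted over the runs since the
last rank change, so a transition resets them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .param_space import ConfigError, InstrumentSpec

__all__ = ["TransitionRules", "next_rank", "default_cutoffs"]


@dataclass(frozen=True)
class TransitionRules:
    """Per-rank cutoffs plus consecutive-run requirements.

    ``promote_cutoffs``/``demote_cutoffs`` are indexed by rank (1-based,
    ascending order). The promotion cutoff must exceed the demotion cutoff
    at every rank, which makes simultaneous promotion and demotion
    impossible. With ``adaptation_enabled`` False the rules are the
    identity on the current rank.
    """

    promote_cutoffs: tuple[float, ...]
    demote_cutoffs: tuple[float, ...]
    n_consec_up: int = 1
    n_consec_down: int = 1
    adaptation_enabled: bool = True

    def __post_init__(self) -> None:
        if len(self.promote_cutoffs) != len(self.demote_cutoffs):
            raise ConfigError("cutoff tables must have equal length")
        for r, (up, down) in enumerate(
            zip(self.promote_cutoffs, self.demote_cutoffs), start=1
        ):
            if up <= down:
                raise ConfigError(
                    f"rank {r}: promotion cutoff ({up}) must exceed "
                    f"demotion cutoff ({down})"
                )
        if self.n_consec_up < 1 or self.n_consec_down < 1:
            raise ConfigError("n_consec_up and n_consec_down must be >= 1")

    def promote_cutoff(self, rank: int) -> float:
        return self.promote_cutoffs[rank - 1]

    def demote_cutoff(self, rank: int) -> float:
        return self.demote_cutoffs[rank - 1]


def next_rank(
    rules: TransitionRules,
    trajectory_tail: list[tuple[int, float]],
    current_rank: int,
    n_ranks: int,
) -> int:
    """Apply the transition rules to the runs since the last rank change.

    ``trajectory_tail`` holds (rank, score) pairs for all runs since the
    last rank change, oldest first; every entry must be at
    ``current_rank``. Promotion is checked before demotion (the cutoff
    ordering invariant means both can never hold at once). The returned
    rank is always within [1, n_ranks].
    """
    if not trajectory_tail:
        raise ValueError("trajectory_tail must be nonempty")
    if any(r != current_rank for r, _ in trajectory_tail):
        raise ValueError(
            "inconsistent trajectory tail: entries at a rank other than the current one"
        )
    if not rules.adaptation_enabled:
        return current_rank

    scores = [s for _, s in trajectory_tail]
    up = rules.promote_cutoff(current_rank)
    down = rules.demote_cutoff(current_rank)
    if (
        current_rank < n_ranks
        and len(scores) >= rules.n_consec_up
        and all(s > up for s in scores[-rules.n_consec_up:])
    ):
        return current_rank + 1
    if (
        current_rank > 1
        and len(scores) >= rules.n_consec_down
        and all(s < down for s in scores[-rules.n_consec_down:])
    ):
        return current_rank - 1
    return current_rank


def default_cutoffs(
    spec: InstrumentSpec,
    z_up: float = 0.5,
    z_down: float = 1.0,
    n_consec_up: int = 1,
    n_consec_down: int = 1,
    adaptation_enabled: bool = True,
) -> TransitionRules:
    """Quantile-anchored default cutoffs for an instrument.

    Promotion cutoff = mu_second + z_up * sigma_second and demotion cutoff
    = mu_second - z_down * sigma_second at each rank. Positive z values
    guarantee the promotion-above-demotion ordering. The real deployed
    cutoff tables are study-specific; these defaults aim at a broad spread
    of ranks rather than at reproducing any particular deployment.
    """
    promote = tuple(rp.mu_second + z_up * rp.sigma_second for rp in spec.rank_params)
    demote = tuple(rp.mu_second - z_down * rp.sigma_second for rp in spec.rank_params)
    return TransitionRules(
        promote_cutoffs=promote,
        demote_cutoffs=demote,
        n_consec_up=n_consec_up,
        n_consec_down=n_consec_down,
        adaptation_enabled=adaptation_enabled,
    )
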