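"""Model parameters, configuration I/O and population-level extrapolation.

An adaptive cognitive assessment (ACA) instrument administers a short test
at a discrete difficulty level ("rank"); harder ranks yield lower scores.
Each rank carries a normal score distribution with separate parameters for
the first-ever execution at that rank and for all subsequent executions,
plus a within-subject lag-1 correlation governing trajectory stability.

Where rank statistics are only available for part of the rank range in a
patient population, the missing entries are extrapolated from healthy
volunteers: means via the average relative patient-vs-HV difference over
shared ranks, SDs via the mean patient coefficient of variation applied to
the HV mean at the missing rank.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LearningParams",
    "DeclineParams",
    "RankParams",
    "InstrumentSpec",
    "RankStatsTable",
    "ConfigError",
    "SimulationConfig",
    "extrapolate_missing_means",
    "extrapolate_missing_sds",
    "generate_synthetic_battery",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """A configuration value violates the model's invariants."""


@dataclass(frozen=True)
class LearningParams:
    """Half-sigmoidal learning/practice-effect multiplier parameters.

    ``maximum`` is the dimensionless asymptote of the multiplier (1.3 means
    a 30% improvement over the first run); ``rate`` (per run, > 0) controls
    how quickly the asymptote is approached.
    """

    maximum: float = 1.3
    rate: float = 0.2

    def __post_init__(self) -> None:
        if self.maximum < 1:
            raise ConfigError(f"learning.maximum must be >= 1, got {self.maximum}")
        if self.rate <= 0:
            raise ConfigError(f"learning.rate must be > 0, got {self.rate}")


@dataclass(frozen=True)
class DeclineParams:
    """Linear cognitive-decline multiplier parameters.

    The expectation multiplier is 1 for the first ``stable_runs`` runs and
    decreases by ``rate_per_run`` (fraction of the expected score) for every
    run thereafter, floored at 0.
    """

    rate_per_run: float = 0.0
    stable_runs: int = 14

    def __post_init__(self) -> None:
        if self.rate_per_run < 0:
            raise ConfigError(
                f"decline.rate_per_run must be >= 0, got {self.rate_per_run}"
            )
        if self.stable_runs < 0 or int(self.stable_runs) != self.stable_runs:
            raise ConfigError(
                f"decline.stable_runs must be a nonnegative integer, got {self.stable_runs}"
            )


@dataclass(frozen=True)
class RankParams:
    """Normal score-distribution parameters at one rank.

    ``mu_first``/``sigma_first`` apply to a subject's first-ever execution
    at the rank; ``mu_second``/``sigma_second`` from the second execution
    onward. ``rho`` is the within-subject lag-1 correlation at the rank.
    """

    mu_first: float
    sigma_first: float
    mu_second: float
    sigma_second: float
    rho: float

    def __post_init__(self) -> None:
        if self.sigma_first <= 0:
            raise ConfigError(f"sigma_first must be > 0, got {self.sigma_first}")
        if self.sigma_second <= 0:
            raise ConfigError(f"sigma_second must be > 0, got {self.sigma_second}")
        if not -1.0 <= self.rho <= 1.0:
            raise ConfigError(f"rho must be in [-1, 1], got {self.rho}")


@dataclass(frozen=True)
class InstrumentSpec:
    """One ACA instrument: per-rank score distributions and score bounds.

    Ranks are 1-based; rank 1 is the easiest. ``rank_params`` is ordered by
    ascending rank. ``score_ceiling`` is None for unbounded-above
    instruments; the short-term-memory instrument is capped at 100.
    """

    name: str
    rank_params: tuple[RankParams, ...]
    score_floor: float = 0.0
    score_ceiling: Optional[float] = None

    def __post_init__(self) -> None:
        if not 5 <= self.n_ranks <= 8:
            raise ConfigError(
                f"instrument {self.name!r}: n_ranks must be in [5, 8], got {self.n_ranks}"
            )
        if self.score_ceiling is not None and self.score_floor >= self.score_ceiling:
            raise ConfigError(
                f"instrument {self.name!r}: score_floor must be < score_ceiling"
            )

    @property
    def n_ranks(self) -> int:
        return len(self.rank_params)

    @property
    def bounds(self) -> tuple[float, Optional[float]]:
        return (self.score_floor, self.score_ceiling)

    def params_at(self, rank: int) -> RankParams:
        if not 1 <= rank <= self.n_ranks:
            raise ValueError(
                f"rank {rank} out of range [1, {self.n_ranks}] for instrument {self.name!r}"
            )
        return self.rank_params[rank - 1]


@dataclass
class RankStatsTable:
    """Per-rank sample mean and SD for one population.

    Upper ranks may be missing entirely (no mean) or have a mean without an
    SD. Backed by plain dicts keyed by 1-based rank index.
    """

    means: dict[int, float] = field(default_factory=dict)
    sds: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rank, sd in self.sds.items():
            if sd <= 0:
                raise ConfigError(f"rank {rank}: SD must be > 0, got {sd}")
            if rank not in self.means:
                raise ConfigError(f"rank {rank}: SD present without a mean")

    @property
    def ranks(self) -> set[int]:
        return set(self.means)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RankStatsTable":
        df = pd.read_csv(path)
        means = {
            int(r.rank): float(r.mean)
            for r in df.itertuples()
            if not pd.isna(r.mean)
        }
        sds = {
            int(r.rank): float(r.sd) for r in df.itertuples() if not pd.isna(r.sd)
        }
        return cls(means=means, sds=sds)

    def to_csv(self, path: str | Path) -> None:
        ranks = sorted(self.means)
        pd.DataFrame(
            {
                "rank": ranks,
                "mean": [self.means[r] for r in ranks],
                "sd": [self.sds.get(r, np.nan) for r in ranks],
            }
        ).to_csv(path, index=False)


def extrapolate_missing_means(
    patient: RankStatsTable, hv: RankStatsTable
) -> RankStatsTable:
    """Fill patient means at ranks only measured in healthy volunteers.

    The mean relative patient-vs-HV difference p over the shared ranks,
    p = mean((mean_patient - mean_HV) / mean_HV), is applied to the HV mean
    at every rank missing from the patient table:
    mean_patient(rank) = mean_HV(rank) * (1 + p). Existing patient entries
    are returned unchanged.
    """
    common = sorted(patient.ranks & hv.ranks)
    if not common:
        raise ValueError("cannot extrapolate: no common ranks between patient and HV")
    for r in common:
        if hv.means[r] == 0:
            raise ValueError(
                f"cannot extrapolate: HV mean is 0 at common rank {r} "
                "(percentage difference undefined)"
            )
    pbar = float(
        np.mean([(patient.means[r] - hv.means[r]) / hv.means[r] for r in common])
    )
    means = dict(patient.means)
    for r in hv.ranks - patient.ranks:
        means[r] = hv.means[r] * (1.0 + pbar)
    return RankStatsTable(means=means, sds=dict(patient.sds))


def extrapolate_missing_sds(
    patient: RankStatsTable, hv: RankStatsTable
) -> RankStatsTable:
    """Fill patient SDs at missing ranks from the patient mean CV.

    The coefficient of variation sd/mean, averaged over patient ranks with
    both statistics, is multiplied by the HV mean at each rank lacking a
    patient SD. Justified when the CV is stable across ranks.
    """
    avail = sorted(set(patient.sds) & set(patient.means))
    if not avail:
        raise ValueError("cannot extrapolate SDs: patient table has no (mean, sd) pair")
    for r in avail:
        if patient.means[r] == 0:
            raise ValueError(
                f"cannot extrapolate SDs: patient mean is 0 at rank {r} (CV undefined)"
            )
    mean_cv = float(np.mean([patient.sds[r] / patient.means[r] for r in avail]))
    sds = dict(patient.sds)
    means = dict(patient.means)
    for r in hv.ranks:
        if r not in sds:
            sds[r] = mean_cv * hv.means[r]
            # an SD without a mean violates the table invariant; carry the
            # HV-extrapolated mean if the patient table lacks one
            means.setdefault(r, hv.means[r])
    return RankStatsTable(means=means, sds=sds)


_INSTRUMENT_NAMES = (
    "numbers",
    "short_term_memory",
    "processing_speed",
    "semantic_recognition",
    "executive_function",
    "psychomotor_speed",
)

# Index of the one ceiling-bounded (0-100) instrument in the default battery.
_CEILING_NAME = "short_term_memory"


def generate_synthetic_battery(seed: int, n_instruments: int = 6) -> list[InstrumentSpec]:
    """Generate a deterministic synthetic battery of ACA instruments.

    Stands in for real reference-study parameter tables. Each instrument
    gets 5-8 ranks; per-rank means decrease with difficulty; the coefficient
    of variation is held roughly stable across ranks; first-execution means
    sit slightly below second-execution means (task novelty); lag-1
    correlations average about 0.76 with fewer than 10% below 0.5; exactly
    one instrument (the short-term-memory task) is ceiling-bounded at 100.
    """
    if n_instruments < 1:
        raise ValueError("n_instruments must be >= 1")
    rng = np.random.default_rng(seed)
    names = [
        _INSTRUMENT_NAMES[i] if i < len(_INSTRUMENT_NAMES) else f"instrument_{i + 1}"
        for i in range(n_instruments)
    ]
    ceiling_idx = names.index(_CEILING_NAME) if _CEILING_NAME in names else 0

    battery: list[InstrumentSpec] = []
    for i, name in enumerate(names):
        has_ceiling = i == ceiling_idx
        n_ranks = int(rng.integers(5, 9))
        mu = float(rng.uniform(75, 90)) if has_ceiling else float(rng.uniform(50, 80))
        cv = float(rng.uniform(0.15, 0.25))
        step = float(rng.uniform(0.82, 0.92))  # per-rank mean decay (harder -> lower)
        ranks = []
        for _ in range(n_ranks):
            mu_second = mu
            sigma_second = cv * mu_second
            first_frac = float(rng.uniform(0.90, 0.97))
            mu_first = first_frac * mu_second
            sigma_first = cv * mu_first
            rho = float(np.clip(rng.normal(0.76, 0.10), 0.30, 0.95))
            ranks.append(
                RankParams(
                    mu_first=mu_first,
                    sigma_first=sigma_first,
                    mu_second=mu_second,
                    sigma_second=sigma_second,
                    rho=rho,
                )
            )
            mu *= step
        battery.append(
            InstrumentSpec(
                name=name,
                rank_params=tuple(ranks),
                score_floor=0.0,
                score_ceiling=100.0 if has_ceiling else None,
            )
        )
    return battery


@dataclass
class SimulationConfig:
    """Full configuration for a simulated ACA study.

    Bundles the instrument battery, the subject-model parameters shared by
    all simulated subjects, the study schedule, the rank-transition cutoff
    scheme and the cohort grid of cognitive-decline rates.
    """

    battery: list[InstrumentSpec]
    instrument: str = "numbers"
    learning: LearningParams = field(default_factory=LearningParams)
    stable_runs: int = 14
    decline_rates: tuple[float, ...] = (0.0, 0.0005, 0.001, 0.0015, 0.002)
    n_subjects: int = 200
    run_in_runs: int = 14
    total_runs: int = 220
    initial_rank: Optional[int] = None  # None -> middle rank of the instrument
    paradigms: tuple[str, ...] = ("fixed_rank", "adaptive_rank")
    z_up: float = 0.5
    z_down: float = 1.0
    n_consec_up_run_in: int = 1
    n_consec_down_run_in: int = 1
    n_consec_up: int = 2
    n_consec_down: int = 2
    decline_threshold: float = 0.30
    confirm_runs: int = 8

    def __post_init__(self) -> None:
        if not 0 <= self.run_in_runs < self.total_runs:
            raise ConfigError(
                f"require 0 <= run_in_runs < total_runs, got "
                f"{self.run_in_runs}, {self.total_runs}"
            )
        if self.n_subjects < 1:
            raise ConfigError(f"n_subjects must be >= 1, got {self.n_subjects}")
        names = [s.name for s in self.battery]
        if self.instrument not in names:
            raise ConfigError(
                f"instrument {self.instrument!r} not in battery {names}"
            )
        for p in self.paradigms:
            if p not in ("fixed_rank", "adaptive_rank"):
                raise ConfigError(f"unknown paradigm {p!r}")

    @property
    def instrument_spec(self) -> InstrumentSpec:
        return next(s for s in self.battery if s.name == self.instrument)


# ---------------------------------------------------------------------------
# configuration (de)serialization


def _config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["battery"] = [asdict(s) for s in config.battery]
    d["decline_rates"] = list(config.decline_rates)
    d["paradigms"] = list(config.paradigms)
    d["learning"] = asdict(config.learning)
    for s in d["battery"]:
        s["rank_params"] = [dict(rp) if isinstance(rp, dict) else rp for rp in s["rank_params"]]
    return d


_RANK_FIELDS = ("mu_first", "sigma_first", "mu_second", "sigma_second", "rho")


def _instrument_from_dict(d: dict, path: str) -> InstrumentSpec:
    try:
        raw_ranks = d["rank_params"]
    except KeyError:
        raise ConfigError(f"{path}: missing field 'rank_params'") from None
    ranks = []
    for j, rp in enumerate(raw_ranks):
        for f in _RANK_FIELDS:
            if f not in rp or rp[f] is None:
                raise ConfigError(
                    f"{path}.rank_params[{j}] (rank {j + 1}): missing field {f!r}"
                )
        try:
            ranks.append(RankParams(**{f: rp[f] for f in _RANK_FIELDS}))
        except ConfigError as e:
            raise ConfigError(f"{path}.rank_params[{j}] (rank {j + 1}): {e}") from None
    try:
        return InstrumentSpec(
            name=d["name"],
            rank_params=tuple(ranks),
            score_floor=d.get("score_floor", 0.0),
            score_ceiling=d.get("score_ceiling"),
        )
    except ConfigError as e:
        raise ConfigError(f"{path}: {e}") from None


def _config_from_dict(d: dict) -> SimulationConfig:
    if "battery" not in d:
        raise ConfigError("config: missing field 'battery'")
    battery = [
        _instrument_from_dict(s, f"battery[{i}]") for i, s in enumerate(d["battery"])
    ]
    learning = LearningParams(**d.get("learning", {}))
    kwargs = {
        k: v
        for k, v in d.items()
        if k not in ("battery", "learning") and v is not None
    }
    for tup in ("decline_rates", "paradigms"):
        if tup in kwargs:
            kwargs[tup] = tuple(kwargs[tup])
    if "initial_rank" in d:
        kwargs["initial_rank"] = d["initial_rank"]
    return SimulationConfig(battery=battery, learning=learning, **kwargs)


def save_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a configuration to YAML (default) or JSON, by file extension."""
    path = Path(path)
    d = _config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def load_config(path: str | Path) -> SimulationConfig:
    """Load a configuration from a YAML or JSON file, validating invariants."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _config_from_dict(d)
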