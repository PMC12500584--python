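"""Survival curves, effect sizes and paradigm comparison.

Time-to-confirmed-decline endpoints are summarized with the Kaplan–Meier
product-limit estimator. Between-cohort responsiveness is quantified with
Cohen's d, both raw (difference in means over the pooled SD) and from an
ANCOVA linear model (endpoint ~ group + baseline, d = group coefficient
over residual SD). A closed-form expected effect size for the fixed-rank
paradigm — the expected end-of-study group difference at a fixed rank over
that rank's score SD — serves as a theoretical reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter

from .param_space import DeclineParams, InstrumentSpec, LearningParams
from .subject_model import decline_multiplier, learning_multiplier
from .trajectory_engine import StudySpec, Trajectory

__all__ = [
    "SurvivalCurve",
    "EffectSizeResult",
    "kaplan_meier",
    "cohens_d_raw",
    "cohens_d_linear_model",
    "theoretical_effect_size",
    "mean_value_series",
    "compare_paradigms",
]


@dataclass
class SurvivalCurve:
    """Kaplan–Meier estimate over the distinct observed times.

    ``survival[i]`` is S(t) just after ``times[i]``; ``at_risk[i]`` counts
    subjects under observation at ``times[i]``; events precede censorings
    at tied times.
    """

    times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    survival: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.n_events,
                "censored": self.n_censored,
                "survival": self.survival,
            }
        )


def kaplan_meier(event_records: list[tuple[float, bool]]) -> SurvivalCurve:
    """Product-limit estimator from (time, event_flag) pairs.

    ``event_flag`` True marks an observed event; False a right-censoring
    time. Censored subjects leave the risk set after their time.
    """
    if not event_records:
        raise ValueError("event_records must be nonempty")
    times = np.asarray([t for t, _ in event_records], dtype=float)
    if np.any(times <= 0):
        raise ValueError("all times must be positive")
    events = np.asarray([bool(e) for _, e in event_records])

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    t = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(t).to_numpy()
    return SurvivalCurve(
        times=t,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        n_events=table["observed"].to_numpy(dtype=int),
        n_censored=table["censored"].to_numpy(dtype=int),
        survival=surv,
    )


def cohens_d_raw(group_a, group_b) -> float:
    """Standardized mean difference (mean_a - mean_b) / pooled SD.

    Pooled SD uses the usual (n_a + n_b - 2)-df pooling of the two sample
    variances. A zero pooled SD yields signed infinity (nan when the means
    are also equal), flagged rather than raised.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if pooled_var == 0:
        return float(np.sign(diff) * np.inf) if diff != 0 else float("nan")
    return float(diff / np.sqrt(pooled_var))


def cohens_d_linear_model(values, group_indicator, baseline_covariate) -> float:
    """ANCOVA effect size: endpoint ~ group + baseline.

    Fits an ordinary least-squares model of the endpoint on a 0/1 group
    indicator adjusting for the baseline value; returns the group
    coefficient divided by the residual SD.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group_indicator, dtype=float)
    b = np.asarray(baseline_covariate, dtype=float)
    if not (y.size == g.size == b.size):
        raise ValueError("values, group_indicator and baseline must share length")
    for grp in (0.0, 1.0):
        if np.sum(g == grp) < 3:
            raise ValueError("need at least 3 observations per group")
    if np.ptp(b) == 0:
        # a constant baseline carries no information; drop it rather than
        # fail on collinearity with the intercept
        X = sm.add_constant(g[:, None], has_constant="add")
    else:
        X = sm.add_constant(np.column_stack([g, b]), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design: group and baseline are not identifiable")
    fit = sm.OLS(y, X).fit()
    resid_sd = np.sqrt(fit.scale)
    return float(fit.params[1] / resid_sd)


def theoretical_effect_size(
    spec: InstrumentSpec,
    rank: int,
    study: StudySpec,
    learning: LearningParams,
    decline_a: DeclineParams,
    decline_b: DeclineParams,
) -> float:
    """Expected fixed-rank effect size between two decline rates.

    d = mu_second(rank) * L(N) * (D_a(N) - D_b(N)) / sigma_second(rank)
    with N the total number of runs: the expected end-of-study difference
    in mean score between the two cohorts at a fixed rank, standardized by
    the rank's marginal score SD.
    """
    rp = spec.params_at(rank)
    n = study.total_runs
    L = learning_multiplier(learning, n)
    da = decline_multiplier(decline_a, n)
    db = decline_multiplier(decline_b, n)
    return float(rp.mu_second * L * (da - db) / rp.sigma_second)


@dataclass(frozen=True)
class EffectSizeResult:
    """One effect-size estimate for a cohort comparison."""

    comparison: str
    paradigm: str
    endpoint: str
    estimator: str
    d: float
    n_a: int
    n_b: int


def mean_value_series(
    trajectories: list[Trajectory], paradigm: str, run_in_runs: int = 14
) -> pd.DataFrame:
    """Cohort mean (and SE) of the tracked variable at every run."""
    from .endpoints import tracked_series

    values = np.vstack(
        [tracked_series(t, paradigm, run_in_runs) for t in trajectories]
    )
    runs = np.arange(run_in_runs + 1, run_in_runs + values.shape[1] + 1)
    return pd.DataFrame(
        {
            "run": runs,
            "mean": values.mean(axis=0),
            "se": values.std(axis=0, ddof=1) / np.sqrt(values.shape[0]),
        }
    )


_ENDPOINT_COLUMNS = {
    "study_end_value": "value_at_study_end",
    "change_from_baseline": "change_from_baseline",
    "percent_change_from_baseline": "percent_change_from_baseline",
}


def compare_paradigms(
    endpoint_tables: dict[tuple[str, float], pd.DataFrame],
    comparisons: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Effect-size table over paradigm x endpoint x estimator x comparison.

    ``endpoint_tables`` maps (paradigm, decline_rate) to a per-subject
    endpoint table (see :func:`acasim.endpoints.endpoint_table`). By
    default every ordered pair of adjacent decline rates plus all pairs
    given explicitly are compared; the d sign convention is
    (slower decline) - (faster decline).
    """
    paradigms = sorted({p for p, _ in endpoint_tables})
    rates_by_paradigm = {
        p: sorted({r for q, r in endpoint_tables if q == p}) for p in paradigms
    }
    rates = rates_by_paradigm[paradigms[0]]
    if any(rates_by_paradigm[p] != rates for p in paradigms):
        raise ValueError(
            "mismatched configurations: paradigms cover different decline rates"
        )
    if comparisons is None:
        comparisons = list(zip(rates[:-1], rates[1:]))
    for a, b in comparisons:
        if a not in rates or b not in rates:
            raise ValueError(f"comparison ({a}, {b}) not covered by the simulated rates")

    rows = []
    for paradigm, (rate_a, rate_b), (endpoint, col) in product(
        paradigms, comparisons, _ENDPOINT_COLUMNS.items()
    ):
        ta = endpoint_tables[(paradigm, rate_a)]
        tb = endpoint_tables[(paradigm, rate_b)]
        label = f"{rate_a:g}_vs_{rate_b:g}"
        a_vals = ta[col].to_numpy(dtype=float)
        b_vals = tb[col].to_numpy(dtype=float)
        base_a = ta["baseline_value"].to_numpy(dtype=float)
        base_b = tb["baseline_value"].to_numpy(dtype=float)
        # percent change is undefined (NaN) for baseline 0; such subjects
        # are excluded from the affected endpoint only
        keep_a, keep_b = np.isfinite(a_vals), np.isfinite(b_vals)
        a_vals, base_a = a_vals[keep_a], base_a[keep_a]
        b_vals, base_b = b_vals[keep_b], base_b[keep_b]
        d_raw = cohens_d_raw(a_vals, b_vals)
        y = np.concatenate([a_vals, b_vals])
        g = np.concatenate([np.zeros(len(a_vals)), np.ones(len(b_vals))])
        base = np.concatenate([base_a, base_b])
        # group 1 is the faster-declining cohort; negate so the sign matches
        # the raw convention mean(slow) - mean(fast)
        d_lm = -cohens_d_linear_model(y, g, base)
        for estimator, d in (("raw", d_raw), ("linear_model", d_lm)):
            rows.append(
                EffectSizeResult(
                    comparison=label,
                    paradigm=paradigm,
                    endpoint=endpoint,
                    estimator=estimator,
                    d=d,
                    n_a=len(a_vals),
                    n_b=len(b_vals),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])
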