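"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: direct scans, explicit product accumulation and
rejection sampling, sharing no code with the package.
"""

import numpy as np


def brute_force_confirmed_decline(series, baseline, threshold=0.30, confirm_runs=8):
    """Exhaustive scan over every window of length ``confirm_runs``."""
    cutoff = baseline * (1.0 - threshold)
    n = len(series)
    for start in range(n - confirm_runs + 1):
        if all(series[start + j] < cutoff for j in range(confirm_runs)):
            return True, start + 1
    return False, n


def brute_force_product_limit(times, events):
    """Product-limit survival estimate, accumulated time by time.

    Returns (distinct_times, survival) with events preceding censorings at
    tied times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    distinct = np.unique(times)
    surv = []
    s = 1.0
    for t in distinct:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & events)
        if at_risk > 0:
            s *= 1.0 - d / at_risk
        surv.append(s)
    return distinct, np.asarray(surv)


def rejection_sample_conditional(
    prev, mu_j, sigma_j, mu_next, sigma_next, rho, rng, n_target=4000, eps_frac=0.05
):
    """Sample score_{j+1} | score_j ~ prev from the joint bivariate normal.

    Draws bivariate pairs and keeps the second coordinate of pairs whose
    first coordinate lands within a narrow window around ``prev``.
    """
    eps = eps_frac * sigma_j
    cov = np.array(
        [
            [sigma_j**2, rho * sigma_j * sigma_next],
            [rho * sigma_j * sigma_next, sigma_next**2],
        ]
    )
    kept = []
    while sum(len(k) for k in kept) < n_target:
        xy = rng.multivariate_normal([mu_j, mu_next], cov, size=400_000)
        sel = np.abs(xy[:, 0] - prev) < eps
        kept.append(xy[sel, 1])
    return np.concatenate(kept)
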