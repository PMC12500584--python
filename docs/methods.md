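# Methods

## Subject model

A subject's score at a given difficulty rank is normally distributed. Each
rank carries four distribution parameters — mean and SD for the *first*
execution at that rank (`mu_first`, `sigma_first`) and for every later
execution (`mu_second`, `sigma_second`) — plus a within-subject lag-1
correlation `rho`. The first/second split reflects the systematic shift
commonly seen between a task's first encounter and subsequent encounters at
the same difficulty; a rank re-visited later in a trajectory uses the
second-execution parameters.

Two deterministic multipliers act on the expectation (not the SD — the
variance parameters describe test-retest noise, which we treat as
independent of the slow mean trends):

- **Learning** `L(run) = max / (1 + (max − 1)·exp(−rate·(run − 1)))`, a
  half-sigmoid with `L(1) = 1` exactly, rising to the asymptote `max`.
  Defaults `max = 1.3`, `rate = 0.2`/run: a 30% eventual improvement with
  ≈90% of it attained by run 14, i.e. essentially saturated by the end of a
  two-week daily run-in. The implementation uses the algebraically
  equivalent form above (rather than the exponent-with-log form) so that
  `L(1)` is exact in floating point.
- **Decline** `D(run) = 1` for `run ≤ stable_runs` (default 14, matching
  the run-in), then `1 − rate_per_run·(run − stable_runs)`, floored at 0.
  With weekly testing, `rate_per_run` of 0.0005/0.001/0.0015/0.002 maps to
  roughly 2.5%/5%/7.5%/10% of performance lost per year. Run indices are
  *global* across phases, so the multipliers are continuous at the
  run-in/evaluation boundary.

Scores evolve as a (generally non-stationary) first-order autoregressive
process: given the previous score at the same rank, the next score is drawn
from the bivariate-normal conditional law

    mean = mu_next + rho · sigma_next · (score_prev − mu_prev) / sigma_prev
    var  = (1 − rho²) · sigma_next²

with run-specific means/SDs on both sides. The first run of a trajectory,
and the first run after any rank change, draw from the marginal normal at
the current rank — the chain does not carry correlation across ranks, since
scores at different difficulty levels are different measurements. Draws are
clamped *after* sampling to the instrument bounds (floor 0; ceiling 100
only on the short-term-memory instrument); this post-hoc clamp, rather than
a truncated-normal renormalization, mirrors how bounded app scores are
produced in practice. The clamp makes the process slightly non-normal near
the bounds; with the default parameter ranges the floor is ≥3 SD from every
rank mean, so the effect is negligible except at the ceiling instrument's
easiest ranks, where a genuine ceiling effect is intended.

## Study model

After each run the transition rules compare the scores accumulated *since
the last rank change* to per-rank cutoffs: promotion when the latest
`n_consec_up` scores all strictly exceed the promotion cutoff (if a harder
rank exists), demotion when the latest `n_consec_down` scores are all
strictly below the demotion cutoff. Promotion is tested first; the ordering
invariant (promotion cutoff > demotion cutoff at every rank) makes the two
criteria mutually exclusive, so the ordering is never load-bearing. Streak
counters reset on every rank change.

Deployed cutoff tables are study-specific and not public, so the package
ships a quantile-anchored default: promotion at `mu_second + 0.5·sigma_second`,
demotion at `mu_second − 1.0·sigma_second` per rank. During the 14-run
daily run-in adaptation is allowed at every run (`n_consec = 1`); in the
evaluation phase the default requires two consecutive qualifying runs,
chosen a priori because at a weekly cadence a confirmation run guards
against rank churn from single noisy tests. Both are independent
configuration fields.

Time between administrations is not modeled explicitly; schedule density
differences must be folded into the learning/decline/correlation
parameters. `build_schedule` converts a horizon in years (1 year = 52
weeks) plus a daily run-in into a run count: 4 years with a 14-day run-in
and weekly testing gives 14 + 206 = 220 runs.

## Synthetic parameter battery

The reference parameter tables from the studies that motivated the model
are not distributable, so `generate_synthetic_battery` builds a seeded
stand-in with the structure those data are described to have:

- 6 instruments, 5–8 ranks each, per-rank means decreasing with difficulty
  (decay factor ~U(0.82, 0.92) per rank step);
- a stable coefficient of variation across ranks (~U(0.15, 0.25) per
  instrument), which is also the empirical justification for the CV-based
  SD extrapolation;
- first-execution means slightly below second-execution means
  (factor ~U(0.90, 0.97));
- lag-1 correlations ~N(0.76, 0.1) clipped to [0.30, 0.95], giving a mean
  near 0.76 with under 10% of values below 0.5;
- exactly one instrument (short-term memory) score-bounded to [0, 100].

What the generator does **not** emulate: between-instrument correlation
within a subject, between-subject heterogeneity in learning/decline
parameters (all subjects in a cohort share them; only the noise realization
differs), rank-dependent correlation structure beyond the clip, dropout and
missing runs, and any calendar-time effects. Passing tests therefore show
that the *mechanism* (rank adaptation amplifying sustained decline)
produces the expected qualitative contrasts under these idealized
conditions — not that any specific real instrument will show effect sizes
of a particular magnitude.

## Population extrapolation

When a patient table lacks upper ranks, means are extrapolated from healthy
volunteers by applying the mean relative patient-vs-HV difference over the
shared ranks to the HV mean at each missing rank. SDs are extrapolated as
(mean patient CV) × (HV mean at the missing rank) — the HV mean *at that
rank*, read as rank-contextual; applying the CV to the already-extrapolated
patient mean instead would change SDs by the cohort-level offset factor and
is easy to add, but the rank-contextual HV anchor is the implemented
interpretation.

## Endpoints

Baseline is the (rank, score) of the last run-in run. The tracked variable
is the score under fixed-rank and the rank under adaptive-rank (scores are
not comparable across ranks). Confirmed decline: the first run whose value
is strictly more than 30% below baseline and stays so for at least 8
consecutive runs (≈2 months of weekly testing); the event time is the
*onset* run of the sustained streak, mirroring confirmed-progression
conventions in neurology trials, and a qualifying streak cut off by study
end does not confirm. Subjects whose tracked variable cannot reach the
threshold (adaptive-rank subjects with baseline rank 1) are retained as
censored and flagged `structural_censor`.

## Analysis

Kaplan–Meier estimation is delegated to `lifelines` (events precede
censorings at tied times, the product-limit convention); an independent
hand-written product-limit scan serves as the oracle in tests. Cohen's *d*
is computed raw (pooled (n_a+n_b−2)-df SD) and from an ANCOVA linear model
(`endpoint ~ group + baseline`, via statsmodels OLS; d = group coefficient
/ residual SD; a constant baseline column is dropped rather than treated as
a collinearity error). The theoretical fixed-rank effect size between two
decline rates is `mu_second·L(N)·(D_a(N) − D_b(N)) / sigma_second` at the
rank of interest — the expected end-of-study mean difference standardized
by the rank's *marginal* SD, a deliberately simple reference that ignores
the AR-induced shrinkage of the end-value variance. No multiplicity control
is applied anywhere: the comparisons are descriptive.

## Numerical and design choices

- RNG: numpy `Generator` streams; cohorts spawn one `SeedSequence` child
  per subject (`spawn_key=(subject_index,)`), so results are
  bit-reproducible and independent of execution order. The CLI derives
  per-(cohort, paradigm) seeds from the master seed the same way.
- The rank of run k+1 is decided by the run-in rules while k+1 is still a
  run-in run and by the evaluation regime afterwards; under fixed-rank the
  evaluation rank therefore equals the baseline rank exactly.
- Percent change from a zero baseline is flagged undefined (NaN in tables)
  rather than raised; such subjects are dropped only from the
  percent-change effect-size cells.
- Zero pooled SD in raw Cohen's d yields signed infinity (NaN when the
  means also tie), flagged rather than raised.

## Problem sizes in the test suite

Monte-Carlo tests use 10⁵ parallel chains (marginal preservation), one
10⁵-step chain (correlation recovery, ±0.03), 20 parameter sets of ~4000
rejection samples (conditional-law equivalence at 3 Monte-Carlo SEs), 500
and 1000 random datasets for the survival and event-detector oracles, and
full-scale directional runs of 200 subjects × 220 runs per cohort under
both paradigms. These sizes make the stochastic assertions comfortably
stable at fixed seeds while keeping the default suite around half a minute.

## Known limitations

Cohort homogeneity (no random effects on learning/decline), a single
instrument per simulated study, no adherence/dropout process, static
cutoffs while expected scores drift (which concentrates subjects at the top
rank once learning saturates — with the default cutoffs the adaptive
paradigm's sensitivity comes from *demotions* under sustained decline), and
qualitative-only correspondence to any published effect-size magnitudes,
which depend on unpublished instrument parameter tables.
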