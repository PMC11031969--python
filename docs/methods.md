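# Methods

This note documents the models implemented in `ceatrial`, the synthetic
trial generator that exercises them, and the numerical conventions and
design choices a user should know before interpreting output.

## Study design assumed

A two-arm cluster-randomised trial: general practices are randomised 1:1
to intervention or usual care, patients are nested in practices and belong
to one of three cohorts — children (< 18), adults (18–64 with
multimorbidity) and older adults (≥ 65).  Observation covers three
12-month periods: p0 (the year before randomisation), p1 (the intervention
year) and p2 (the follow-up year).  EQ-5D-5L health states are collected at
baseline and 12 months only; service-use counts and component costs are
available for all three periods.  The economic evaluation covers the adult
and older cohorts (children complete proxy/youth questionnaire versions and
are excluded); the service-use models use all randomised patients
(intention to treat).

## Utilities and QALYs

A value set is a total map from the 3,125 states to utilities with
utility("11111") = 1 enforced at load time.  Additive sets are expanded
from per-dimension decrement tables (level-1 decrement must be 0,
decrements non-decreasing in level, so worsening one dimension never
raises utility).

Per-patient QALYs use the trapezium rule over 0/12/24 months with the
24-month utility imputed:

* survivors, control arm: u24 = u12 (carry-forward in every scenario);
* survivors, intervention arm: u24 = u12·(1 − d), d ∈ {0, 0.05, 0.15};
* decedents (deaths are placed between 12 and 24 months): u24 = 0, and the
  trapezium is still applied over months 12–24, i.e. a linear decline to
  zero rather than censoring at an unrecorded death date.  This is an
  interpretive choice; the alternative (zero area in year 2) would lower
  decedent QALYs by u12/2/(1+r).

Year-1 quantities are undiscounted; year-2 quantities are divided by
(1 + r) with r = 0.05/year (no continuous or mid-year discounting).
Missing 12-month utilities are never imputed at this stage: the profile
carries NaN and the downstream mixed model handles them by complete-case
likelihood, valid under missingness-at-random given the baseline utility,
which is exactly how the generator creates them.

Note on the decay: it is multiplicative ("u24 is 95% of u12"), so for the
rare worse-than-death states (u12 < 0) a positive decay moves u24 toward 0
— upward.  Monotone-decline properties therefore hold for survivors with
non-negative u12; aggregate incremental QALYs still decrease in d.

## Costs

Discounted two-year total per patient
= (p1 hospital + specialist + pharmaceutical)
+ payment·index (intervention arm only, year 1)
+ (p2 components)/(1 + r).

The per-participant payment defaults to A$1,000 with `index_factor`
converting it to analysis-year prices; the bundled default 1.026 produces
A$1,026, consistent with indexation of a 2018-19 payment to 2021/22 unit
prices.  Baseline (p0) costs appear in the descriptive cost table only and
never enter incremental totals.

## Incremental analysis

* ΔE: REML linear mixed model `qaly ~ arm + u0` with a practice random
  intercept (statsmodels MixedLM).  When the practice variance component
  collapses to the boundary — common here, because adjusting for baseline
  utility absorbs most practice-level variation in QALYs — the model falls
  back to the OLS fit of the same mean structure with an explicit warning;
  the point estimate is then the fixed-effects ANCOVA estimate.
* ΔC: difference in arm means of discounted totals.
* ICER = ΔC/ΔE when the two share sign; "dominant" (cheaper & more
  effective) or "dominated" (costlier & less effective) otherwise;
  ΔE = 0 is "undefined".  ΔC = 0 ties resolve to the dominance label.
* Bootstrap: B = 1,000 resamples of participants with replacement *within
  arm*; each replicate recomputes ΔC on the full resample and ΔE by the
  same covariate-adjusted mean difference with the random effect dropped
  (resampling breaks cluster membership), costs and QALYs taken jointly
  per participant so their covariance is preserved.  Percentile (not BCa)
  95% intervals.  A cluster bootstrap (resampling whole practices within
  arm) is available via `cluster=True` but is off by default, matching the
  participant-level convention; note that with strong practice-level cost
  heterogeneity the participant-level percentile CI for ΔC undercovers
  (measured ≈ 83% at the default generator settings vs ≈ 96% when
  practice-level rate heterogeneity is absent) — a known property of
  ignoring clustering, not a bug in the resampler.
* CEP quadrants: x = ΔE, y = ΔC; ties are deterministic — ΔE = 0 counts as
  east (more effective), ΔC = 0 as south (cheaper) — so proportions always
  sum to exactly 1.
* CEAC uses the strict inequality λ·ΔE − ΔC > 0; at-threshold equality
  counts as not cost-effective.  Default grid 0–100,000 in steps of 1,000
  (always containing 50,000).
* Sensitivity scenarios reuse the *same* resample indices, so the ΔC
  column of every replicate cloud is bitwise identical across decays and
  only the QALY side moves.
* Subgroup analyses (adults; older adults) are configuration-driven
  filters re-running the full CEA per cohort, not interaction models.

## Service-use models

Counts enter a patient-period long format (baseline vs follow-up, where
the two-year window pools p1 + p2) and are fitted by log-link NB2 maximum
likelihood, `count ~ group + time + group×time`, with cluster-robust
(practice) standard errors; IRR = exp(interaction).  Periods enter without
an exposure offset: the common time effect absorbs the longer pooled
window, leaving the interaction invariant — and likewise invariant to any
common rescaling of counts.

No Python library in the stack provides a negative binomial mixed model
with practice and patient random intercepts, and such fits are numerically
delicate in any case.  Under the generator's multiplicative log-normal
random intercepts — which scale both periods of a patient equally and are
independent of the randomised arm — the marginal interaction coefficient
equals the conditional IRR, so the robust marginal NB estimator recovers
the same parameter; the tests verify this by simulation (200 trials) and
against an independent `MASS::glm.nb` fit in R.  The contract is parameter
recovery, not coefficient identity with any particular mixed-model
implementation.

## The synthetic-data generator

Per patient i in practice j, cohort c:

* latent health h_i ~ N(0, 0.25); practice utility intercept
  a_j ~ N(0, 0.05); occasion noise N(0, 0.12).
* latent utility u*_t = μ_c + a_j + h_i + ε_t, with the additive
  intervention effect δ = 0.05 at 12 months in the intervention arm;
  truncated to the value-set range and snapped to the nearest
  representable state so downstream code always consumes states, never
  raw utilities.  Cohort means μ = 0.88 / 0.57 / 0.64 (child/adult/older).
* counts: NB2 with log rate = log r_ck + b_j + g_i + τ_p + 1[int, p>0]·log IRR_k,
  b_j ~ N(0, 0.15), g_i of sd 0.50 negatively correlated (ρ = 0.5) with
  h_i so sicker patients use more services; the log-normal effects are
  mean-centred so marginal means equal the configured rates exactly.
  Baseline rates per patient-year loosely follow a multimorbid primary-care
  population (e.g. ED ≈ 0.6–0.75, specialist ≈ 30–40, pharmaceuticals
  ≈ 45–60 for adults/older); conditional dispersions (ED 2.5, admissions
  2.5, nights 12, specialist 0.7, pharmaceuticals 0.25) reproduce the
  strong overdispersion seen in such data.  Default IRRs are the observed
  two-year effects (ED 0.90, admissions 0.95, nights 0.80, specialist
  0.99, pharmaceuticals 1.00).
* costs = unit prices × counts + gamma noise (night A$2,000, admission
  A$1,500, ED A$600, specialist item A$90, pharmaceutical item A$43), so
  hospital costs are dominated by night stays and count effects propagate
  into costs; amounts are rounded to cents so CSV round-trips are exact.
* deaths: Bernoulli per cohort (0.2% / 2% / 8%), placed in period 2 only,
  so 12-month states exist for all year-1 completers.
* missingness: the 12-month state is masked with probability
  logit⁻¹(−1.2 − 1.5·u0) (≈ 10%), drawn from a separate random stream so
  the mask is reproducible from (u0, seed) alone — missing-at-random by
  construction.

What the generator does **not** emulate: informative missingness,
arm-dependent death, within-period event timing (decedents keep a full
p2 count record, consistent with intention-to-treat), pandemic-era
utilisation shocks, or item-level price schedules.  Passing tests
therefore demonstrate correctness of the analysis machinery under a
well-specified clustered data-generating process, not robustness to those
real-data complications.

Because costs are mechanically coupled to counts, the default night-stay
IRR of 0.80 makes the intervention arm cheaper on average, so a typical
simulated trial shows dominance overall — the structure (older-cohort
savings through hospital costs, positive QALY gain, CEAC well above 50% at
A$50,000) rather than any particular published point estimate, which
patient-level confidentiality makes unreproducible anyway.

## Problem sizes and determinism

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical (config, seed) pairs give
byte-identical datasets and pipeline artifacts.  The simulation studies in
the test suite use 200 full-size trials (n = 1,044, 20 practices) for the
incremental-QALY and IRR recovery checks, 200 bootstrap replicates per
trial for coverage, 100 reduced trials for the cost-CI calibration check,
and 10,000 replicates for the analytic CEAC oracle; these sizes make the
Monte-Carlo error small relative to the tolerances tested while keeping
the suite fast.  The acceptance script runs one full-size trial with
B = 1,000.
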