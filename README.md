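# ceatrial

Within-trial cost-effectiveness analysis for clustered two-arm trials.

`ceatrial` implements the economic-evaluation chain used to judge whether a
primary-care intervention tested in a cluster-randomised trial is value for
money over a two-year horizon:

* **EQ-5D-5L scoring** — five dimensions × five levels describe
  5⁵ = 3,125 health states; a pluggable *value set* maps each state to a
  utility anchored at 1 (full health) and 0 (dead), possibly negative for
  states worse than death.
* **QALYs by the trapezium method** — with assessments at 0 and 12 months
  and no 24-month questionnaire, the 12-month utility is carried forward
  for survivors (optionally decayed by 5% or 15% in sensitivity scenarios)
  and decedents are assigned 0 at 24 months:

  QALY = (u₀ + u₁₂)/2 + (u₁₂ + u₂₄)/2 · 1/(1+r),  r = 5%/year.

* **Discounted costs** — hospital, specialist and pharmaceutical components
  per 12-month period, plus an indexed A$1,000 per-participant intervention
  payment in year 1; year-2 amounts discounted one year.
* **Bootstrap incremental analysis** — ΔE from a linear mixed model of
  QALYs on arm with baseline utility as covariate and a practice random
  intercept; ΔC from arm means; the ICER ΔC/ΔE (or a dominance label);
  1,000 participant-level bootstrap replicates preserving the per-patient
  cost–effect covariance feed the cost-effectiveness plane and the
  acceptability curve CEAC(λ) = P(λ·ΔE − ΔC > 0), evaluated against the
  Australian A$50,000/QALY threshold.
* **Service-use rate ratios** — log-link negative binomial regression on
  the patient-period long format (group, time, group×time) with
  cluster-robust standard errors; the exponentiated interaction is the
  incidence rate ratio (IRR) of the intervention.
* **A synthetic-trial generator** — a seeded simulator of the full design
  (20 practices 1:1, cohorts of 58 children / 315 adults / 671 older
  adults, practice and patient heterogeneity, overdispersed counts,
  right-skewed costs coupled to hospital use, deaths concentrated in the
  older cohort, missing-at-random 12-month states), so every stage is
  testable without any external data.

The library is aimed at health economists and trial statisticians who want
a reproducible, scriptable version of this analysis; everything is driven
from Python, with a thin `ceatrial` CLI for batch runs.

## Worked example

```python
from ceatrial import (GeneratorConfig, generate_trial, load_value_set,
                      build_analysis_table, analyse, ceac, default_wtp_grid)

vs = load_value_set("synthetic-au-range")      # additive set spanning [-0.676, 1]
trial = generate_trial(GeneratorConfig(seed=1), vs)
table = build_analysis_table(trial, vs, payment=1000, index_factor=1.026)
res = analyse(table, B=1000, seed=1)
curve = ceac(res.replicates, default_wtp_grid())
print(res.delta_cost, res.delta_qaly, res.icer, curve.at(50_000))
```

prints (seed 1):

```
incremental cost  ΔC = A$-515  (95% CI -2792 to 1805)
incremental QALYs ΔE = +0.061  (95% CI 0.029 to 0.089)
ICER: dominant
P(cost-effective) at A$50,000/QALY: 99.3%
```

i.e. in this simulated trial the intervention saves about A$515 per patient
(driven by fewer hospital nights) and gains 0.061 QALYs, so it *dominates*
usual care — cheaper and more effective — and has a 99% probability of
positive net monetary benefit at the A$50,000/QALY threshold.  The
`examples/` directory walks through each capability (simulation, scoring,
QALYs and costs, bootstrap CEA, sensitivity scenarios, service-use IRRs)
with short narrative scripts.

From the shell:

```bash
ceatrial simulate --seed 1 --out trial.csv
ceatrial run --seed 1 --out results/     # full pipeline + manifest
ceatrial ceac --replicates results/replicates_combined_decay0.csv
```

Every run writes a `manifest.json` with the configuration, seed and SHA-256
checksums of all artifacts; identical config + seed reproduces every CSV
byte-for-byte.

## Value sets

Two additive value sets ship with the package: `toy`
(utility = 1 − 0.05·Σ(level−1)) and `synthetic-au-range`, a synthetic
decrement table calibrated so utilities span exactly [−0.676, 1] — the
range of the published Australian EQ-5D-5L value set — for offline use.
The published tariff itself is not redistributed; load it from a
user-supplied CSV (`state,utility` lookup or `dimension,level,decrement`
table) with `load_value_set(path)`, which validates the full-health anchor
and completeness at load time.

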