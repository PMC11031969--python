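"""Incremental cost-effectiveness with a participant-level bootstrap.

ΔE is the baseline-adjusted incremental QALY from a practice-level mixed
model; ΔC the difference in mean discounted total costs.  1,000 paired
bootstrap replicates (resampled within arm, costs and QALYs jointly per
participant) give percentile CIs, the cost-effectiveness plane quadrants,
and the acceptability curve against an A$50,000/QALY threshold.
"""

import warnings

from ceatrial import (
    GeneratorConfig,
    analyse,
    build_analysis_table,
    ceac,
    cep_summary,
    default_wtp_grid,
    generate_trial,
    load_value_set,
)

warnings.filterwarnings("ignore")

vs = load_value_set("synthetic-au-range")
trial = generate_trial(GeneratorConfig(seed=1), vs)
table = build_analysis_table(trial, vs, payment=1000, index_factor=1.026)
res = analyse(table, B=1000, seed=1)

print(f"incremental cost  ΔC = A${res.delta_cost:+.0f}  "
      f"(95% CI {res.ci_cost[0]:.0f} to {res.ci_cost[1]:.0f})")
print(f"incremental QALYs ΔE = {res.delta_qaly:+.3f}  "
      f"(95% CI {res.ci_qaly[0]:.3f} to {res.ci_qaly[1]:.3f})")
print(f"ICER: {res.icer if isinstance(res.icer, str) else f'A${res.icer:,.0f}/QALY'}")

quads = cep_summary(res.replicates)
print("\ncost-effectiveness plane quadrants (share of 1,000 replicates):")
for q, label in (("NE", "costlier & more effective"), ("SE", "cheaper & more effective"),
                 ("NW", "costlier & less effective"), ("SW", "cheaper & less effective")):
    print(f"  {q} ({label}): {quads[q]:.1%}")

curve = ceac(res.replicates, default_wtp_grid())
print(f"\nP(cost-effective) at A$50,000/QALY: {curve.at(50_000):.1%}")
print("(the probability the intervention has positive net monetary benefit)")
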