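"""Score EQ-5D-5L health states under a pluggable value set.

A five-digit code records the impairment level (1–5) on mobility,
self-care, usual activities, pain/discomfort and anxiety/depression; a
value set maps each of the 5^5 = 3,125 states to a utility anchored at
1 (full health) and 0 (dead), possibly negative for states worse than
death.
"""

from ceatrial import enumerate_states, load_value_set, score_state

states = enumerate_states()
print(f"representable health states: {len(states)} "
      f"(first {states[0].code}, last {states[-1].code})")

vs = load_value_set("synthetic-au-range")  # synthetic set spanning [-0.676, 1]
print(f"\nvalue set {vs.name!r}: range [{vs.min_utility:.3f}, {vs.max_utility:.1f}]")
for code in ("11111", "21121", "33333", "55555"):
    print(f"  utility({code}) = {score_state(code, vs):+.3f}")
print("utility 1 = full health; below 0 = rated worse than death")
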