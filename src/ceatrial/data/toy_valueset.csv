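# Toy additive value set for tests and examples: utility = 1 - 0.05 * sum(level - 1).
# Worst state 55555 scores 1 - 0.05*20 = 0.0.
dimension,level,decrement
mobility,1,0.0
mobility,2,0.05
mobility,3,0.10
mobility,4,0.15
mobility,5,0.20
self_care,1,0.0
self_care,2,0.05
self_care,3,0.10
self_care,4,0.15
self_care,5,0.20
usual_activities,1,0.0
usual_activities,2,0.05
usual_activities,3,0.10
usual_activities,4,0.15
usual_activities,5,0.20
pain_discomfort,1,0.0
pain_discomfort,2,0.05
pain_discomfort,3,0.10
pain_discomfort,4,0.15
pain_discomfort,5,0.20
anxiety_depression,1,0.0
anxiety_depression,2,0.05
anxiety_depression,3,0.10
anxiety_depression,4,0.15
anxiety_depression,5,0.20
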