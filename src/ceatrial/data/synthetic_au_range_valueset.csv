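# SYNTHETIC additive EQ-5D-5L decrement table.
# Calibrated so that utilities span exactly [-0.676, 1] — the range of the
# published Australian EQ-5D-5L value set — but the per-dimension decrements
# are invented for offline testing and are NOT the published tariff.
dimension,level,decrement
mobility,1,0.0
mobility,2,0.044
mobility,3,0.093
mobility,4,0.210
mobility,5,0.350
self_care,1,0.0
self_care,2,0.042
self_care,3,0.088
self_care,4,0.195
self_care,5,0.314
usual_activities,1,0.0
usual_activities,2,0.037
usual_activities,3,0.079
usual_activities,4,0.168
usual_activities,5,0.264
pain_discomfort,1,0.0
pain_discomfort,2,0.058
pain_discomfort,3,0.123
pain_discomfort,4,0.261
pain_discomfort,5,0.412
anxiety_depression,1,0.0
anxiety_depression,2,0.047
anxiety_depression,3,0.100
anxiety_depression,4,0.213
anxiety_depression,5,0.336
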