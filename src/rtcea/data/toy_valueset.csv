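dimension,level,decrement
mobility,2,-0.04
mobility,3,-0.09
mobility,4,-0.16
mobility,5,-0.27
self_care,2,-0.03
self_care,3,-0.08
self_care,4,-0.14
self_care,5,-0.21
usual_activities,2,-0.04
usual_activities,3,-0.07
usual_activities,4,-0.13
usual_activities,5,-0.20
pain_discomfort,2,-0.05
pain_discomfort,3,-0.11
pain_discomfort,4,-0.19
pain_discomfort,5,-0.30
anxiety_depression,2,-0.04
anxiety_depression,3,-0.10
anxiety_depression,4,-0.17
anxiety_depression,5,-0.26
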