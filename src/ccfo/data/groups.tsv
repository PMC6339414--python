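group	root_ccfo_id
seen-by-professional-allied-to-medicine	116
physical-examination	13
activity-exercise-pattern	1123
ability-to-move	1121
activity-of-daily-living	1124
eating-feeding-drinking	1126
social-and-personal-history	115
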