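surface	ccfo_id	intrinsic
anxiety	21
anxious	21
depression	22
depressed	22
pain	1111
painful	1111
physical therapy	116
occupational therapy	116
transfers	1122
transfers independently	1122	able
kneels	11211
able to kneel	11211	able
unable to kneel	11211	unable
difficulty running	11213	with-difficulty
able to run	11213	able
unable to run	11213	unable
run	11213
difficulty standing up	11214	with-difficulty
unable to stand up	11214	unable
able to stand up	11214	able
stand up	11214
stagger	11215
ambulate independently	112121	able
steady gait	112121	able
unsteady gait	112121	with-difficulty
bed-ridden	1121221
stretcher	1121221
paralysis	1121222
paralyzed	1121222
paraplegic	1121222	paraplegic
quadriplegic	1121222	quadriplegic
wheelchair	1121223
scooter	1121223
w/c	1121223
wheel chair	1121223
light exercise	11231
moderate exercise	11232
vigorous exercise	11233
gets no exercise	11234
no exercise	11234
community activities	11241
physical activity	11243
personal care	11244
daily routine	11245
drives	112411
driving	112411
leisure activities	112412
hobbies	112412
shopping	112413
housework	112414
vacuuming	112414
dusting	112414
washing dishes	112414
bathes	112441
bathing	112441
able to bathe	112441	able
unable to bathe	112441	unable
dresses	112442
able to dress	112442	able
independent with dressing	112442	able
needs help with dressing	112442	with-difficulty
dependent for dressing	112442	unable
unable to dress	112442	unable
difficulty dressing	112442	with-difficulty
shoes	112442
ties shoes	112442
able to wash own hair	112443	able
unable to wash own hair	112443	unable
difficulty washing own hair	112443	with-difficulty
clean appearance	112443
personal grooming	112443
neatly dressed	112443
well-groomed	112443
well-groomed without assistance	112443	able
good personal hygiene	112443
toileting	112444
toilets	112444
feeds self	112445
feeds	112445
walks	112471
able to walk	112471	able
unable to walk	112471	unable
walks unaided	112472
cane	112473
walker	112473
walking aid	112473
able to walk downstairs	1124711	able
walks downstairs	1124711
able to walk upstairs	1124713	able
unable to walk upstairs	1124713	unable
walks upstairs	1124713
climb stairs	1124713
appetite	11261
poor appetite	11261
incontinent	11271
continent	11272
incontinent of urine	112711
urinary incontinence	112711
incontinent of stool	112712
bowel incontinence	112712
continent of urine	112721
continent of stool	112722
calm	113331
happy	113332
nervous	113333
sad	113334
occupational maladjustment	1154
work limitations	1154
socially isolated	11531
social withdrawal	11531
dyspnea on exertion	131
dyspnea	131
sob	131
short of breath	131
muscle weakness	133
muscle strength	133
motor strength	133
decreased strength	133
grip strength	133
deconditioned	134
deconditioning	134
bmi	135
weight loss	135
underweight	135
fit and well	1323
robust	1323
unwell	1324
generally unwell	1324
comorbid	1326
comorbidities	1326
sustains energy	132221
lack of energy	132222
tired	132222
fatigue	132222
lack energy	132222
tiredness	132222
sleepiness	132222
drowsiness	132222
exhaustion	132222
exhaust	132222
wear out	132222
drain	132222
weary	132222
calf weakness	1331
quadriceps weakness	1334
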