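instrument	aliases	scale_min	scale_max	lo	hi	label	order	direction	flags
morse	morse fall scale|annual fall scale|mrt|morse	0	125	0	24	low fall risk	0	higher-is-frailer
morse	morse fall scale|annual fall scale|mrt|morse	0	125	25	44	moderate risk	1	higher-is-frailer
morse	morse fall scale|annual fall scale|mrt|morse	0	125	45	125	high fall risk	2	higher-is-frailer
tinetti	tinetti assessment measures|tinetti assessment|tinetti	0	28	25	28	low fall risk	0	lower-is-frailer
tinetti	tinetti assessment measures|tinetti assessment|tinetti	0	28	19	24	some risk for falls	1	lower-is-frailer
tinetti	tinetti assessment measures|tinetti assessment|tinetti	0	28	0	18	high risk for falls	2	lower-is-frailer
braden	braden scale|braden	6	23	19	23	no risk	0	lower-is-frailer
braden	braden scale|braden	6	23	15	18	mild risk	1	lower-is-frailer
braden	braden scale|braden	6	23	13	14	moderate risk	2	lower-is-frailer
braden	braden scale|braden	6	23	10	12	high risk	3	lower-is-frailer
braden	braden scale|braden	6	23	6	9	very high risk	4	lower-is-frailer
fim	functional independence measure|fim	1	7	7	7	complete independence	0	lower-is-frailer
fim	functional independence measure|fim	1	7	6	6	modified independence	1	lower-is-frailer
fim	functional independence measure|fim	1	7	5	5	supervision or set-up	2	lower-is-frailer
fim	functional independence measure|fim	1	7	4	4	minimal contact assistance	3	lower-is-frailer
fim	functional independence measure|fim	1	7	3	3	moderate assistance	4	lower-is-frailer
fim	functional independence measure|fim	1	7	2	2	maximal assistance	5	lower-is-frailer
fim	functional independence measure|fim	1	7	1	1	total assistance	6	lower-is-frailer
katz	katz index adl|katz adl|katz	0	6	6	6	high functioning, patient is independent	0	lower-is-frailer
katz	katz index adl|katz adl|katz	0	6	1	5	partially dependent	1	lower-is-frailer
katz	katz index adl|katz adl|katz	0	6	0	0	low functioning, patient is very dependent	2	lower-is-frailer
barthel-100	barthel index|barthel	0	100	70	100	independent	0	lower-is-frailer
barthel-100	barthel index|barthel	0	100	0	69	needs significant physical/supervisory assistance	1	lower-is-frailer
iadl-item	iadl item	0	2	2	2	without assistance	0	lower-is-frailer
iadl-item	iadl item	0	2	1	1	with assistance	1	lower-is-frailer
iadl-item	iadl item	0	2	0	0	unable	2	lower-is-frailer
lawton	instrumental activities of daily living scale|iadl screen|lawton|iadl	0	8	0	8	lower score indicates a higher level of dependence	-1	lower-is-frailer	continuous
faq	functional activity questionnaire|faq	0	30	0	4	no significant impairment	0	higher-is-frailer
faq	functional activity questionnaire|faq	0	30	5	30	significant impairment in instrumental activities of daily living	1	higher-is-frailer
adl-screen	adl screen	0	18	18	18	patient independent	0	lower-is-frailer	caution
adl-screen	adl screen	0	18	6	6	patient very independent	1	lower-is-frailer	caution
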