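ccfo_id	sctid	name	parent_id	role	axis	level
1		clinical finding		hierarchical-group
11		clinical history finding	1	hierarchical-group
12		instrument finding	1	hierarchical-group
13		physical examination finding	1	hierarchical-group
14		demographics	1	hierarchical-group
2		diagnosis		hierarchical-group
21		anxiety diagnosis	2	document-expected	frequency
22		depression diagnosis	2	document-expected	frequency
111	130979001	alteration in comfort finding	11	hierarchical-group
1111		alteration in comfort: pain finding	111	document-expected	frequency
112		physical function finding	11	hierarchical-group
113	116367006	psychological finding	11	hierarchical-group
115	365448001	social and personal history finding	11	hierarchical-group
116		seen by professional allied to medicine finding	11	document-expected	none
1121		ability to move finding	112	hierarchical-group
1122	714882001	ability to transfer location finding	112	document-expected	ability
1123		activity exercise pattern finding	112	hierarchical-group
1124	118233009	finding of activity of daily living	112	hierarchical-group
1126		eating feeding and drinking ability finding	112	hierarchical-group
1127		continence of bowel and bladder finding	112	hierarchical-group
11211		able to kneel finding	1121	document-expected	ability
11212		mobility status finding	1121	hierarchical-group
11213		ability to run finding	1121	document-expected	ability
11214		ability to stand finding	1121	document-expected	ability
11215		impairment of balance finding	1121	document-expected	frequency
112121		able to mobilize finding	11212	document-expected	ability
112122		immobility finding	11212	hierarchical-group
1121221		bed-ridden finding	112122	document-expected	none
1121222		paralysis finding	112122	document-expected	none
1121223		wheelchair bound finding	112122	document-expected	none
11231		enjoys light exercise finding	1123	document-expected	frequency
11232		enjoys moderate exercise finding	1123	document-expected	frequency
11233		enjoys vigorous exercise finding	1123	document-expected	frequency
11234		gets no exercise finding	1123	document-expected	none
11241		ability to perform community living activities finding	1124	document-expected	ability
11243		ability to perform general purpose physical activity finding	1124	document-expected	ability
11244	284774007	able to perform personal care activities finding	1124	document-expected	ability
11245		able to carry out daily routine finding	1124	document-expected	ability
11247		walking finding	1124	hierarchical-group
112411		ability to drive a car finding	11241	document-expected	ability
112412		ability to participate in leisure activities finding	11241	document-expected	ability
112413		ability to perform shopping activities finding	11241	document-expected	ability
112414		ability to perform domestic activities finding	11241	document-expected	ability
112441		able to perform bathing activity finding	11244	document-expected	ability
112442		able to perform dressing activity finding	11244	document-expected	ability
112443		able to perform personal grooming activity finding	11244	document-expected	ability
112444		able to perform toileting activity finding	11244	document-expected	ability
112445		able to perform feeding activity finding	11244	document-expected	ability
112471		able to walk finding	11247	document-expected	ability
112472		no aid for walking finding	11247	document-expected	none
112473		walking aid use finding	11247	document-expected	none
1124711		able to walk downstairs finding	112471	document-expected	ability
1124713		able to walk upstairs finding	112471	document-expected	ability
11261		appetite finding	1126	document-expected	frequency
11271		incontinence finding	1127	document-expected	frequency
11272		continence finding	1127	document-expected	none
112711		urinary incontinence finding	11271	document-expected	frequency
112712		bowel incontinence finding	11271	document-expected	frequency
112721		urinary continence finding	11272	document-expected	none
112722		bowel continence finding	11272	document-expected	none
11333		mental state finding	113	hierarchical-group
113331		calm finding	11333	document-expected	frequency
113332		happy finding	11333	document-expected	frequency
113333		nervous finding	11333	document-expected	frequency
113334		sad finding	11333	document-expected	frequency
1153		social interaction finding	115	hierarchical-group
1154		occupational maladjustment finding	115	document-expected	frequency
11531		impaired social interaction finding	1153	document-expected	frequency
131	60845006	dyspnea on exertion finding	13	document-expected	frequency
132	365275006	general well-being finding	13	hierarchical-group
133	713514005	muscle weakness of limb finding	13	document-expected	frequency
134	31031000119102	physical deconditioning finding	13	document-expected	frequency
135	107647005	weight finding	13	document-expected	none
1323		fit and well finding	132	document-expected	frequency
1324		generally unwell finding	132	document-expected	frequency
1326		comorbid condition count finding	132	document-expected	none
13222		energy level finding	132	hierarchical-group
132221		able to sustain energy level finding	13222	document-expected	ability
132222		lack of energy finding	13222	document-expected	frequency
1331		calf weakness finding	133	document-expected	frequency
1334		quadriceps weakness finding	133	document-expected	frequency
141		patient age finding	14	demographic
142		sex finding	14	hierarchical-group
1422		indeterminate sex finding	142	demographic
4		qualifier values		hierarchical-group
41	371148001	ability interpretation qualifier value	4	qualifier-value	ability
411	371157007	able with difficulty qualifier value	41	qualifier-value	ability	with-difficulty
412	371150009	able qualifier value	41	qualifier-value	ability	able
413	371151008	unable qualifier value	41	qualifier-value	ability	unable
42	272519000	absent finding qualifier value	4	qualifier-value	absent	absent
43	288524001	courses qualifier value	4	qualifier-value	course
431	90734009	chronic qualifier value	43	qualifier-value	course	chronic
432	424572001	clinical course with short duration qualifier value	43	qualifier-value	course	short-duration
433	385315009	sudden onset qualifier value	43	qualifier-value	course	sudden-onset
44	272123002	frequency qualifier value	4	qualifier-value	frequency
441	27732004	high frequency qualifier value	44	qualifier-value	frequency	high-frequency
442	255218000	mid-frequency qualifier value	44	qualifier-value	frequency	mid-frequency
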