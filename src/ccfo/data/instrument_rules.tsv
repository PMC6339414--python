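instrument	item	weight	points	concept1	qual1	course1	concept2	qual2
katz	bathing	1	1	112441	able
katz	bathing	1	0	112441	unable
katz	dressing	1	1	112442	able
katz	dressing	1	0	112442	unable
katz	toileting	1	1	112444	able
katz	toileting	1	0	112444	unable
katz	feeding	1	1	112445	able
katz	feeding	1	0	112445	unable
katz	transfer	1	1	1122*	able
katz	transfer	1	0	1122*	unable
katz	continence	1	1	112721	present		112722	present
katz	continence	1	1	112721	present		112712	absent
katz	continence	1	1	112711	absent		112722	present
katz	continence	1	1	112711	absent		112712	absent
katz	continence	1	0	11271*	present
barthel	continence	1	2	112721	present		112722	present
barthel	continence	1	2	112721	present		112712	absent
barthel	continence	1	2	112711	absent		112722	present
barthel	continence	1	2	112711	absent		112712	absent
barthel	continence	1	0	11271*	present
barthel	bathing	1	2	112441	uq|able
barthel	bathing	1	1	112441	with-difficulty
barthel	bathing	1	0	112441	unable
barthel	dressing	1	2	112442	uq|able
barthel	dressing	1	1	112442	with-difficulty
barthel	dressing	1	0	112442	unable
barthel	grooming	1	2	112443	uq|able
barthel	grooming	1	1	112443	with-difficulty
barthel	grooming	1	0	112443	unable
barthel	toileting	1	2	112444	uq|able
barthel	toileting	1	1	112444	with-difficulty
barthel	toileting	1	0	112444	unable
barthel	feeding	1	2	112445	uq|able
barthel	feeding	1	1	112445	with-difficulty
barthel	feeding	1	0	112445	unable
barthel	transfer	1	2	1122*	uq|able|with-difficulty
barthel	transfer	1	0	1122*	absent|unable
barthel	mobility	1	3	112121	able
barthel	mobility	1	3	112472	uq|able
barthel	mobility	1	2	112121	with-difficulty
barthel	mobility	1	2	112473	present
barthel	mobility	1	1	1121223	present
barthel	mobility	1	0	112121	unable
barthel	mobility	1	0	1121221	present
barthel	stairs	1	2	1124713	able
barthel	stairs	1	2	1124711	able
barthel	stairs	1	0	1124713	unable
sf36:general-health	q1	1	100	1323	uq|high-frequency
sf36:general-health	q1	1	75	1323	mid-frequency
sf36:general-health	q1	1	50	1324	absent
sf36:general-health	q1	1	25	1324	mid-frequency
sf36:general-health	q1	1	0	1324	uq|high-frequency
sf36:general-health	q2	1	100	1323	uq|high-frequency	sudden-onset
sf36:general-health	q2	1	75	1323	mid-frequency	sudden-onset
sf36:general-health	q2	1	50	1324	absent
sf36:general-health	q2	1	25	1324	mid-frequency
sf36:general-health	q2	1	0	1324	uq|high-frequency
sf36:pain	q21	1	100	1111	absent
sf36:pain	q21	1	50	1111	mid-frequency
sf36:pain	q21	1	0	1111	uq|high-frequency
sf36:pain	q22	1	100	1111	absent		11245	able
sf36:pain	q22	1	75	1111	mid-frequency		11245	able
sf36:pain	q22	1	50	1111	uq|high-frequency		11245	able
sf36:pain	q22	1	25	1111	mid-frequency		11245	with-difficulty
sf36:pain	q22	1	0	1111	uq|high-frequency		11245	unable|with-difficulty
sf36:physical-functioning	q3	1	100	11233	uq|high-frequency
sf36:physical-functioning	q3	1	100	11213	able
sf36:physical-functioning	q3	1	50	11233	mid-frequency
sf36:physical-functioning	q3	1	0	11234	present
sf36:physical-functioning	q3	1	0	11213	unable
sf36:physical-functioning	q3	1	0	11233	absent
sf36:physical-functioning	q4	1	100	11232	uq|high-frequency
sf36:physical-functioning	q4	1	50	11232	mid-frequency
sf36:physical-functioning	q4	1	0	11234	present
sf36:physical-functioning	q4	1	0	11213	unable
sf36:physical-functioning	q4	1	0	11232	absent
sf36:physical-functioning	q5	1	100	11243	able
sf36:physical-functioning	q5	1	100	112413	able
sf36:physical-functioning	q5	1	50	11243	with-difficulty
sf36:physical-functioning	q5	1	50	112413	with-difficulty
sf36:physical-functioning	q5	1	0	11243	unable
sf36:physical-functioning	q5	1	0	112413	unable
sf36:physical-functioning	q6-7	2	200	1124713	able
sf36:physical-functioning	q6-7	2	100	1124713	with-difficulty
sf36:physical-functioning	q6-7	2	0	1124713	unable
sf36:physical-functioning	q8	1	100	11211	able
sf36:physical-functioning	q8	1	50	11211	with-difficulty
sf36:physical-functioning	q8	1	0	11211	unable
sf36:physical-functioning	q9-11	3	300	112471	able
sf36:physical-functioning	q9-11	3	200	112471	with-difficulty
sf36:physical-functioning	q9-11	3	0	112471	unable
sf36:physical-functioning	q12	1	100	11244*	able
sf36:physical-functioning	q12	1	50	11244*	with-difficulty
sf36:physical-functioning	q12	1	0	11244*	unable
sf36:role-physical	q13-15	3	300	1154	absent
sf36:role-physical	q13-15	3	150	1154	mid-frequency
sf36:role-physical	q13-15	3	0	1154	uq|high-frequency
sf36:role-physical	q16	1	100	11245	able
sf36:role-physical	q16	1	50	11245	with-difficulty
sf36:role-physical	q16	1	0	11245	unable
sf36:role-emotional	q17-19	3	300	1154	absent		113*	any
sf36:role-emotional	q17-19	3	150	1154	mid-frequency		113*	any
sf36:role-emotional	q17-19	3	0	1154	uq|high-frequency		113*	any
sf36:energy-fatigue	q23-31	1	100	132221	able
sf36:energy-fatigue	q23-31	1	100	132222	absent
sf36:energy-fatigue	q23-31	1	50	132221	with-difficulty
sf36:energy-fatigue	q23-31	1	50	132222	mid-frequency
sf36:energy-fatigue	q23-31	1	0	132221	unable
sf36:energy-fatigue	q23-31	1	0	132222	uq|high-frequency
sf36:emotional-well-being	q24-26	2	200	113331	uq|high-frequency
sf36:emotional-well-being	q24-26	2	200	113333	absent
sf36:emotional-well-being	q24-26	2	200	21	absent
sf36:emotional-well-being	q24-26	2	150	113331	mid-frequency
sf36:emotional-well-being	q24-26	2	100	113333	mid-frequency
sf36:emotional-well-being	q24-26	2	50	113331	absent
sf36:emotional-well-being	q24-26	2	0	113333	uq|high-frequency
sf36:emotional-well-being	q24-26	2	0	21	present
sf36:emotional-well-being	q25-30	3	300	113332	uq|high-frequency
sf36:emotional-well-being	q25-30	3	300	113334	absent
sf36:emotional-well-being	q25-30	3	300	22	absent
sf36:emotional-well-being	q25-30	3	225	113332	mid-frequency
sf36:emotional-well-being	q25-30	3	150	113334	mid-frequency
sf36:emotional-well-being	q25-30	3	75	113332	absent
sf36:emotional-well-being	q25-30	3	0	113334	uq|high-frequency
sf36:emotional-well-being	q25-30	3	0	22	present
sf36:social-functioning	q32	1	100	11241	able
sf36:social-functioning	q32	1	50	11241	with-difficulty
sf36:social-functioning	q32	1	0	11241	unable
sf36:social-functioning	q20	1	100	11531	absent
sf36:social-functioning	q20	1	50	11531	mid-frequency
sf36:social-functioning	q20	1	0	11531	uq|high-frequency
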