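patient_id	endotype	ema_class	anca	timepoint	sex	organ_systems	activity_score
C1 Patient 3	A	GPA	PR3	Diagnosis	F	Skin, ENT, lung, CNS, MSK, renal	33
C1 Patient 23	A	GPA	PR3	Relapse	F	ENT, lung, renal	8
C1 Patient 24	A	GPA	PR3	Relapse	F	Skin, eye, ENT, lung, MSK, renal	19
C1 Patient 6	A	GPA	PR3	Diagnosis	F	Skin, eye, ENT, lung, MSK, renal	30
C1 Patient 25	A	GPA	PR3	Diagnosis	F	Lung, renal	19
C1 Patient 7	A	GPA	PR3	Diagnosis	M	Skin, lung, MSK, renal	21
C1 Patient 17	A	GPA	PR3	Diagnosis	M	ENT, lung, renal	26
C1 Patient 11	A	GPA	MPO	Diagnosis	F	Skin, ENT, lung, renal	30
C1 Patient 22	A	GPA	MPO	Diagnosis	F	Skin, lung, renal	20
C1 Patient 14	A	uAAV	PR3	Diagnosis	M	Eye, ENT, renal	21
C1 Patient 21	A	uAAV	PR3	Diagnosis	F	Lung, renal	23
C1 Patient 13	A	uAAV	MPO	Diagnosis	F	Renal	18
C1 Patient 19	A	uAAV	MPO	Diagnosis	M	Skin, ENT, lung	10
C1 Patient 10	B	GPA	MPO	Diagnosis	F	Lung, MSK	10
C1 Patient 15	B	GPA	MPO	Diagnosis	F	ENT, renal	17
C1 Patient 1	B	GPA	PR3	Diagnosis	F	Skin, ENT, lung, renal	23
C1 Patient 8	B	GPA	PR3	Diagnosis	F	Skin, lung, MSK, renal	21
C1 Patient 29	B	GPA	PR3	Relapse	M	ENT, lung, renal	10
C1 Patient 20	B	MPA	MPO	Diagnosis	F	Renal	12
C1 Patient 28	B	MPA	MPO	Diagnosis	F	Skin, MSK, renal	16
C1 Patient 16	B	MPA	MPO	Diagnosis	M	Skin, eye, renal	16
C1 Patient 12	B	MPA	PR3	Diagnosis	M	Eye, renal	15
C1 Patient 4	B	PAN	NEG	Diagnosis	F	Skin	9
C1 Patient 26	B	PAN	NEG	Diagnosis	M	Skin, eye, ENT	12
C1 Patient 30	B	uAAV	MPO	Relapse	F	Eye, renal	19
C1 Patient 9	B	UCV	NEG	Diagnosis	M	Eye, MSK	5
C1 Patient 18	B	uAAV	PR3	Diagnosis	F	ENT	7
C1 Patient 27	other	GPA	PR3	Diagnosis	F	Skin, ENT, lung, MSK, renal	32
C1 Patient 2	other	GPA	MPO	Diagnosis	M	Skin, lung, cardiac, renal	20
C1 Patient 5	other	uAAV	MPO	Relapse	F	Lung	11
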