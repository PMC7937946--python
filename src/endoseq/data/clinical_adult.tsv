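patient_id	endotype	ema_class	anca	timepoint	sex	organ_systems	activity_score
Adult Patient 2	A	GPA	PR3	Diagnosis	F	Systemic, skin, eyes, ENT, chest, abdominal, renal	45
Adult Patient 5	A	GPA	PR3	Diagnosis	M	ENT, chest, renal	18
Adult Patient 3	A	COMP/GBM	PR3	Diagnosis	M	Systemic, ENT, renal	19
Adult Patient 4	A	MPA	MPO	Diagnosis	F	Systemic, skin, abdominal, renal	26
Adult Patient 6	A	MPA	MPO	Diagnosis	M	Systemic, skin, renal	17
Adult Patient 8	B	MPA	PR3	Diagnosis	M	Lungs, kidneys	16
Adult Patient 9	B	MPA	MPO	Diagnosis	F	Systemic, skin, eyes, abdominal, chest, renal	31
Adult Patient 7	B	GPA	NEG	Diagnosis	M	Lungs	5
Adult Patient 10	B	OSV	NEG	Diagnosis	M	Systemic, skin	9
Adult Patient 11	B	EGPA	NEG	Diagnosis	M	ENT, chest, abdominal, neurological	25
Adult Patient 1	other	MPA	MPO	Diagnosis	M	Systemic, renal, ENT	18
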