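sample_id	tissue	temperature_c	pool_size
iBAT_10C_r1	iBAT	10	2
iBAT_10C_r2	iBAT	10	2
iBAT_10C_r3	iBAT	10	2
iBAT_22C_r1	iBAT	22	2
iBAT_22C_r2	iBAT	22	2
iBAT_22C_r3	iBAT	22	2
iBAT_34C_r1	iBAT	34	2
iBAT_34C_r2	iBAT	34	2
iBAT_34C_r3	iBAT	34	2
ingSAT_10C_r1	ingSAT	10	2
ingSAT_10C_r2	ingSAT	10	2
ingSAT_10C_r3	ingSAT	10	2
ingSAT_22C_r1	ingSAT	22	2
ingSAT_22C_r2	ingSAT	22	2
ingSAT_22C_r3	ingSAT	22	2
ingSAT_34C_r1	ingSAT	34	2
ingSAT_34C_r2	ingSAT	34	2
ingSAT_34C_r3	ingSAT	34	2
Liver_10C_r1	Liver	10	2
Liver_10C_r2	Liver	10	2
Liver_10C_r3	Liver	10	2
Liver_22C_r1	Liver	22	2
Liver_22C_r2	Liver	22	2
Liver_22C_r3	Liver	22	2
Liver_34C_r1	Liver	34	2
Liver_34C_r2	Liver	34	2
Liver_34C_r3	Liver	34	2
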