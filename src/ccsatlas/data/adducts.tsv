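name	polarity	mass_shift	charge	training
[M+H]+	+	1.00727646688	1	1
[M+Na]+	+	22.98922070099	1	1
[M+NH4]+	+	18.03382556789	1	1
[M+H-H2O]+	+	-17.00328821686	1	1
[M+H-2H2O]+	+	-35.01385290060	1	0
[M+CH3OH+H]+	+	33.03349121476	1	0
[M+ACN+H]+	+	42.03382556789	1	0
[M+ACN+Na]+	+	64.01576980200	1	0
[M+2Na-H]+	+	44.97116494982	1	0
[M-H]-	-	-1.00727646688	-1	1
[M+Na-2H]-	-	20.97466779667	-1	1
[M+HCOO]-	-	44.99820283646	-1	1
[M+CH3COO]-	-	59.01385290060	-1	0
[M-H-H2O]-	-	-19.01784115062	-1	0
[M+Cl]-	-	34.96940125991	-1	0
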