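# Nineteen HLA-A2 / Alzheimer's disease case-control studies: labels, populations,
# typing techniques and sample totals as printed.  Per-study 2x2 carrier cells were
# never published, so the *_pos/*_neg columns are intentionally blank; they exist so
# the file shares the study-table schema used by the meta-analysis reader.
label	population	typing_method	cases_total	controls_total	cases_pos	cases_neg	controls_pos	controls_neg
Henschke et al., 1978	Caucasian	serology	34	239
Sulkava et al., 1980	Caucasian	serology	32	35
Wilcox et al., 1980	Caucasian	serology	18	342
Whalley et al., 1980	Caucasian	serology	14	64
Majsky and Vojtechovsky, 1983	Caucasian	serology	38	301
Reed et al., 1983	Caucasian	serology	44	100
Reisner et al., 1983	Caucasian	serology	52	305
Renvoize, 1984	Caucasian	serology	124	458
Endo et al., 1986	Asian	serology	122	66
Small and Matsuyama, 1986	Caucasian	serology	36	25
Payami et al., 1991	Caucasian	serology	54	263
Middleton et al., 1999	Caucasian	molecular	95	45
Small et al., 1999	Caucasian	molecular	479	233
Harris et al., 2000	Caucasian	molecular	178	161
Lehmann et al., 2001	Caucasian	molecular	55	73
Araria-Goumidi et al., 2002	Caucasian	molecular	451	477
Listi et al., 2006	Caucasian	molecular	460	266
Ma et al., 2008	Asian	molecular	160	167
Guerini et al., 2009	Caucasian	molecular	173	258
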