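# Genes contributing more than 0.1% to the cohesion score between the
# Alzheimer's disease and HLA-A concept profiles, with the printed per-gene
# contribution percentage and the printed profile weights (4 significant figures).
gene	percentage	weight_in_AD	weight_in_HLA_A
HLA-A	38.870	1.257E-6	3.990E-2
APLP2	21.170	4.900E-3	5.546E-6
APP	17.115	7.000E-3	3.176E-6
HLA-DRB1	5.576	3.333E-6	2.200E-3
CD8A	3.116	1.434E-5	3.000E-4
ICAM1	2.115	5.694E-6	5.000E-4
HLA-B	1.904	1.067E-6	2.300E-3
HLA-C	1.721	1.472E-6	1.500E-3
CD4	0.611	2.812E-5	2.807E-5
IFNG	0.391	6.326E-6	7.995E-5
HFE	0.223	2.891E-6	9.967E-5
IL1B	0.176	2.309E-5	9.881E-6
IL2	0.170	8.815E-6	2.494E-5
TYR	0.165	2.515E-6	8.474E-5
WT1	0.147	1.599E-6	1.000E-4
SELL	0.138	1.748E-6	1.000E-4
ITGB2	0.135	4.105E-6	4.252E-5
ITGAL	0.128	2.750E-6	6.013E-5
CD80	0.124	4.628E-6	3.470E-5
CD86	0.123	3.332E-6	4.798E-5
SELP	0.113	2.683E-6	5.478E-5
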