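# Intermediate nodes of the seed-expanded protein-interaction subnetwork,
# sorted by z-score as printed: background degree (links), background edge
# total, links to seed nodes, subnetwork edge total, and the printed z-score
# (truncated to two decimals).
node	links	links_in_background	links_to_seed	links_in_subnetwork	z
FUT4	3	11429	2	29	22.86
ICAM5	4	11429	2	29	19.77
PRTN3	9	11429	2	29	13.10
IL2RA	22	11429	3	29	12.47
ICAM3	10	11429	2	29	12.41
VIL2	32	11429	3	29	10.25
ITGAM	15	11429	2	29	10.06
EZR	34	11429	3	29	9.93
KNG1	22	11429	2	29	8.23
RANBP9	22	11429	2	29	8.23
A2M	24	11429	2	29	7.86
PTPRC	35	11429	2	29	6.42
GRB2	196	11429	2	29	2.13
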