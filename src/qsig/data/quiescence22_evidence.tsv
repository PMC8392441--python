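gene	log2FC	q_value	leading_edges	centrality_score	designation	cohorts
CCL5	2.75622625	6.40e-7	5	1.726356886	low	CB572+CB482
CCN3	1.159158799	0.003129394	0	2.369572457	high	CB572+CB482
CDH11	0.924409835	0.001008869	2	0.017134571	low	CB572+CB482
COL17A1	1.159975436	0.002670111	0	2.021417131	high	CB572+CB482
FPR3	2.954316158	3.43e-8	0	2.487201841	high	CB572
HMGCS2	1.36731073	0.000805151	2	0.004347429	low	CB572+CB482
IGFBP5	1.115110029	0.00391699	0	2.801887967	high	CB572+CB482
KLK8	1.33535789	7.97e-5	3	1.277111171	low	CB482
MGAM	1.391777411	0.042802637	0	2.039476442	high	CB572+CB482
MUC5AC	1.422900799	0.000379937	0	2.021250734	high	CB572
OASL	1.151350653	0.023043447	2	2.819995388	high	CB572+CB482
PLAT	1.053223792	0.031200647	4	2.391649253	high	CB572
PTGFR	1.228190238	0.004757316	2	2.315990672	high	CB482
PTGS2	1.429349462	0.022239393	3	2.233337779	high	CB482
PTPRH	1.065756445	0.001072713	0	2.487144917	high	CB572
PTPRN2	1.878824513	2.86e-5	0	2.607454659	high	CB572
RSAD2	1.765109846	8.21e-7	3	0.021323383	low	CB572+CB482
SERPINA1	1.203836437	7.93e-6	3	2.928302569	high	CB482
SERPINA3	1.255309782	0.00051306	2	0.008651795	low	CB572
SERPINE1	1.423828199	0.013356874	8	2.933522416	high	CB572
TNFRSF10C	1.136170418	0.013356874	0	2.021292344	high	CB482
VWA5A	1.412217075	0.001530294	2	0.00434743	low	CB482
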