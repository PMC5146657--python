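accessions	species	g0g1_mean	ratio	ploidy_level	cv_percent
Sba_1,Sba_2,Sba_4	S. babylonica	22182	2.07	4x	3.85
Sba_5,Sba_7,Sba_9	S. babylonica	21500	2.00	4x	3.87
Sba_10,Sba_11	S. babylonica	22341	2.08	4x	3.4
Sba_13,Sba_14	S. babylonica	21213	1.98	4x	4.04
Sba_15,Sba_17	S. babylonica	21731	2.02	4x	3.95
Sma_2	S. matsudana	9931	0.92	2x	4.49
Sma_1,Sma_3,Sma_5	S. matsudana	22470	2.09	4x	3.9
Sma_6,Sma_9	S. matsudana	20529	1.91	4x	4.93
Sma_7,Sma_11	S. matsudana	11826	1.10	2x	4.78
Sma_16	S. matsudana	11697	1.09	2x	4.68
Sma_18,Sma_21,Sma_26	S. matsudana	22366	2.08	4x	2.61
Sin_47	S. integra	10920	1.02	2x	4.96
Sin_74,Sin_99	S. integra	11457	1.07	2x	4.94
Sin_134	S. integra	10900	1.01	2x	4.94
Sin_137,Sin_221	S. integra	9947	0.93	2x	4.85
Sin_270	S. integra	22557	2.10	4x	4.35
Sin_491	S. integra	10686	1.00	2x	4.88
Sin_551	S. integra	10345	0.96	2x	4.77
Sin_578	S. integra	11401	1.06	2x	4.86
Sin_579	S. integra	11275	1.05	2x	4.74
Sin_608	S. integra	10354	0.96	2x	4.93
Ssu_1	S. suchowensis	10441	0.97	2x	4.97
Ssu_2	S. suchowensis	10739	1.00	2x	4.81
Ssu_17,Ssu_38	S. suchowensis	10878	1.01	2x	4.38
Ssu_47	S. suchowensis	11133	1.04	2x	4.56
Ssu_50	S. suchowensis	10502	0.98	2x	4.9
Ssu_69	S. suchowensis	11349	1.06	2x	3.61
Ssu_90	S. suchowensis	15753	1.47	3x	4.12
Ssu_99	S. suchowensis	11681	1.09	2x	4.57
Ssu_101	S. suchowensis	9712	0.90	2x	4.92
Ssu_107	S. suchowensis	11103	1.03	2x	4.95
Ssu_120	S. suchowensis	11380	1.06	2x	4.49
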