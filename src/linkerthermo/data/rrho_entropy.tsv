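# Total RRHO entropies -TS_NMA and ZPVE (kJ/mol) at 300 K per force field.
linker	mts_nma_charmm36m	zpve_charmm36m	mts_nma_ff14sb	zpve_ff14sb
AP	-180.3	776.1	-180.4	791.4
(AP)3	-343.2	1808	-343.2	1854
(AP)4	-424.4	2324	-424.4	2386
(AP)5	-505.5	2840	-505.6	2917
(AP)7	-667.7	3871	-667.9	3980
(AP)10	-910.9	5419	-911.5	5574
GS	-175.0	629.8	-174.7	635.7
(GS)2	-254.3	997.8	-257.5	1008
(GS)3	-332.4	1366	-334.7	1383
(GS)4	-410.5	1734	-411.9	1757
(GS)5	-488.7	2102	-489.2	2132
(GS)7	-644.9	2838	-643.8	2881
(GS)10	-879.1	3943	-875.8	4004
GG	-167.5	543.7	-162.7	548
(GG)2	-238.0	827.4	-226.4	836.1
(GG)3	-308.5	1111	-290.2	1124
(GG)5	-449.7	1678	-417.6	1700
(GG)7	-590.8	2246	-545.1	2277
(GG)10	-802.6	3097	-736.3	3141
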