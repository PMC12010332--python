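# Schlitter entropies -TS (kJ/mol) at 300 K; CHARMM36m mean and sd over 3 replicas.
linker	mts_charmm36m	mts_charmm36m_sd	mts_ff14sb
AP	-73.86	1.851	-75.18
(AP)3	-320.4	1.998	-312.7
(AP)4	-473.0	2.093	-454.5
(AP)5	-624.9	2.879	-591.7
(AP)7	-907.5	5.580	-855.9
(AP)10	-1374	5.527	-1280
GS	-95.07	0.05388	-101.3
(GS)2	-245.4	0.4466	-256.0
(GS)3	-391.1	0.7934	-408.9
(GS)4	-546.1	0.3896	-567.3
(GS)5	-690.9	0.6436	-715.8
(GS)7	-993.5	0.8001	-1023
(GS)10	-1398	37.05	-1474
GG	-80.04	0.07399	-89.17
(GG)2	-171.2	0.1303	-190.9
(GG)3	-271.6	0.4293	-296.3
(GG)5	-496.0	0.8243	-528.3
(GG)7	-716.0	0.7531	-748.8
(GG)10	-1004.79	37.29	-1088
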