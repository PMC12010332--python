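# Solvation free energies A_solv (kJ/mol) at 300 K, mean and sd; NA = not available.
linker	asolv_charmm36m	asolv_charmm36m_sd	asolv_ff14sb	asolv_ff14sb_sd
AP	-66.72	0.215	-75.14	0.474
(AP)3	-168.8	0.893	-176.9	1.607
(AP)4	-166.4	2.118	-218.0	1.937
(AP)5	-160.9	2.989	-196.4	2.175
(AP)7	-254.2	1.538	-221.5	1.404
(AP)10	-293.2	3.802	-366.2	9.591
GS	-93.14	0.324	-94.94	0.458
(GS)2	-137.9	0.916	-149.5	1.153
(GS)3	-169.6	1.893	-169.0	0.87
(GS)4	-219.2	0.916	-215.6	1.929
(GS)5	-237.4	1.726	-260.2	2.763
(GS)7	-312.0	2.822	-304.2	2.522
(GS)10	-413.1	3.948	-390.0	20.28
GG	-87.57	0.134	-82.16	0.325
(GG)2	-122.7	0.347	-117.4	0.672
(GG)3	-154.5	0.763	-150.4	0.973
(GG)5	-221.5	1.806	-221.3	2.029
(GG)7	-276.0	1.676	-255.7	2.467
(GG)10	-400.5	3.247	NA	NA
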