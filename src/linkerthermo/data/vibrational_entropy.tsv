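# Vibrational entropies -TS_vib (kJ/mol) at 300 K per force field.
linker	mts_vib_charmm36m	mts_vib_ff14sb
AP	-85.37	-85.34
(AP)3	-237.1	-236.9
(AP)4	-314.9	-314.7
(AP)5	-393.3	-393.3
(AP)7	-551.7	-551.8
(AP)10	-790.7	-791.1
GS	-80.61	-80.32
(GS)2	-153.5	-156.7
(GS)3	-227.2	-229.5
(GS)4	-301.9	-303.2
(GS)5	-377.1	-377.5
(GS)7	-528.6	-527.4
(GS)10	-757.8	-754.1
GG	-75.07	-70.14
(GG)2	-139.6	-127.9
(GG)3	-206.2	-187.7
(GG)5	-341.9	-309.7
(GG)7	-479.2	-433.3
(GG)10	-686.8	-620.4
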