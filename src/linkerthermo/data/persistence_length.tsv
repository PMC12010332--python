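# Persistence lengths (nm): three replicas (CHARMM36m) and single run (ff14SB+OPC).
linker	lp_charmm36m_r1	lp_charmm36m_r2	lp_charmm36m_r3	lp_ff14sb
AP	3.93	3.96	3.97	4.25
(AP)3	11.8	12.1	12.0	13.9
(AP)4	13.7	13.8	13.9	16.7
(AP)5	15.6	15.9	15.9	20.2
(AP)7	16.6	17.0	16.5	23.3
(AP)10	15.6	16.3	16.8	26.8
GS	3.35	3.36	3.37	3.32
(GS)2	4.16	4.11	4.14	3.55
(GS)3	4.30	4.42	4.28	3.42
(GS)4	4.32	4.33	4.37	3.32
(GS)5	4.31	4.32	4.29	3.34
(GS)7	4.23	4.26	4.23	3.34
(GS)10	3.76	4.07	3.92	3.36
GG	4.14	4.12	4.13	3.82
(GG)2	4.43	4.40	4.43	4.14
(GG)3	4.56	4.53	4.49	4.10
(GG)5	4.46	4.37	4.43	3.98
(GG)7	4.33	4.28	4.29	3.93
(GG)10	4.17	4.45	4.10	3.89
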