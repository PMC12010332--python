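# Linker-only potential energies U (kJ/mol), mean and sd, per force field.
linker	U_charmm36m	U_charmm36m_sd	U_ff14sb	U_ff14sb_sd
AP	248.89	17.909	118.76	17.829
(AP)3	937.86	28.040	520.00	27.926
(AP)4	1282.2	31.939	720.25	31.632
(AP)5	1626.9	35.565	920.67	35.041
(AP)7	2317.8	43.145	1326.0	41.401
(AP)10	3341.8	56.727	1922.6	48.534
GS	115.36	20.669	-2.0180	20.981
(GS)2	325.71	30.248	74.984	31.851
(GS)3	533.77	38.532	145.28	42.866
(GS)4	738.92	47.369	209.73	54.629
(GS)5	940.94	57.424	275.43	64.653
(GS)7	1336.8	79.927	386.25	88.643
(GS)10	1895.0	118.60	547.69	110.87
GG	20.728	16.540	-35.118	18.691
(GG)2	141.07	24.276	14.730	26.800
(GG)3	259.05	31.523	61.557	35.183
(GG)5	486.63	51.053	146.46	53.431
(GG)7	697.67	76.513	223.37	70.953
(GG)10	985.87	114.56	322.94	98.627
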