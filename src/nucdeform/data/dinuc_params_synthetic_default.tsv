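dinuc	roll0	tilt0	twist0	slide0	shift0	k_roll	k_tilt	k_slide	k_shift	n_obs
AA	0.5	-1.5	35.3	-0.1	-0.05	0.045	0.08	3	4.5	1800
AC	0.6	-0.2	32	-0.6	0.1	0.05	0.09	3.5	5	1200
AG	4	-1.6	31.5	-0.3	0.1	0.04	0.075	2.8	4.2	1100
AT	0.9	0	30.5	-0.7	0	0.06	0.1	4	5.5	900
CA	5.3	0.4	35	1.3	0.1	0.02	0.05	1.5	3	1300
CC	4.3	0.1	33.2	0.5	0.05	0.035	0.07	2.2	4	1000
CG	5.5	0	34	0.7	0	0.02	0.05	1.4	3	800
CT	4	1.6	31.5	-0.3	-0.1	0.04	0.075	2.8	4.2	1100
GA	1.7	-1.3	37	-0.1	-0.1	0.035	0.07	2.5	4	1150
GC	0.1	0	37.5	0.4	0	0.03	0.06	2	3.5	950
GG	4.3	-0.1	33.2	0.5	-0.05	0.035	0.07	2.2	4	1000
GT	0.6	0.2	32	-0.6	-0.1	0.05	0.09	3.5	5	1200
TA	4	0	38	0.1	0	0.018	0.045	1.3	2.8	700
TC	1.7	1.3	37	-0.1	0.1	0.035	0.07	2.5	4	1150
TG	5.3	-0.4	35	1.3	-0.1	0.02	0.05	1.5	3	1300
TT	0.5	1.5	35.3	-0.1	0.05	0.045	0.08	3	4.5	1800
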