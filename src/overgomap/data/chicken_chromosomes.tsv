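name	class	length_mb	n_overgos	flag
GGA1	macro	200.99	21
GGA2	macro	154.87	12
GGA3	macro	113.66	98
GGA4	macro	94.23	12
GGA5	macro	62.24	4
GGA6	intermediate	37.40	4
GGA7	intermediate	38.38	4
GGA8	intermediate	30.67	4
GGA9	intermediate	25.55	3
GGA10	intermediate	22.56	3
GGA11	micro	21.93	3
GGA12	micro	20.54	3
GGA13	micro	18.91	3
GGA14	micro	15.82	2
GGA15	micro	12.97	2
GGA16	micro	0.43	4	a
GGA17	micro	11.18	2
GGA18	micro	10.93	2
GGA19	micro	9.94	2
GGA20	micro	13.99	2
GGA21	micro	6.96	2
GGA22	micro	3.94	2
GGA23	micro	6.04	2
GGA24	micro	6.40	2
GGA25	micro	2.03	2
GGA26	micro	5.10	2
GGA27	micro	4.84	2
GGA28	micro	4.51	2
LGE22C19W28_E50C23	linkage_group	0.90	2
GGAW	sex	0.26	1
GGAW_random	sex	0.73	1	b
GGAZ	sex	74.60	6
GGAUn_random	unplaced	63.87	1	a
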