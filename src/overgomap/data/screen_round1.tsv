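name	n_overgos_used	n_successful	n_positive_bacs	flag
GGA1	21	8	58
GGA2	12	5	29
GGA3	98	23	192
GGA4	12	6	77
GGA5	4	4	34
GGA6	4	1	8
GGA7	4	3	25
GGA8	4	0	0
GGA9	3	0	0
GGA10	3	1	7
GGA11	3	3	36
GGA12	3	2	8
GGA13	3	1	6
GGA14	2	0	0
GGA15	2	2	17
GGA16	4	1	18	a
GGA17	2	2	14
GGA18	2	1	18
GGA19	2	1	12
GGA20	2	1	7
GGA21	2	1	7
GGA22	2	0	0
GGA23	2	1	3
GGA24	2	1	13
GGA25	2	0	0
GGA26	2	1	11
GGA27	2	1	1
GGA28	2	1	7
LGE22C19W28_E50C23	2	0	0
GGAW	1	1	15
GGAW_random	1	0	0	b
GGAZ	6	5	17
GGAUn_random	1	1	15	a
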