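Codon	Count	RSCU
UUU	233	1.43
UUC	93	0.57
UUA	229	2.42
UUG	80	0.85
CUU	102	1.08
CUC	36	0.38
CUA	96	1.01
CUG	25	0.26
AUU	201	1.32
AUC	103	0.68
AUA	163	1.5
AUG	54	0.5
GUU	107	1.57
GUC	17	0.25
GUA	116	1.7
GUG	33	0.48
UCU	108	2.26
UCC	37	0.77
UCA	69	1.44
UCG	15	0.31
CCU	67	1.82
CCC	27	0.73
CCA	44	1.2
CCG	9	0.24
ACU	93	1.84
ACC	28	0.55
ACA	73	1.45
ACG	8	0.16
GCU	101	1.82
GCC	46	0.83
GCA	63	1.14
GCG	12	0.22
UAU	87	1.25
UAC	52	0.75
UAA	8	1.6
UAG	2	0.4
CAU	45	1.08
CAC	38	0.92
CAA	48	1.41
CAG	20	0.59
AAU	76	1.2
AAC	51	0.8
AAA	67	1.51
AAG	22	0.49
GAU	44	1.19
GAC	30	0.81
GAA	53	1.36
GAG	25	0.64
UGU	25	1.61
UGC	6	0.39
UGA	71	1.45
UGG	27	0.55
CGU	15	1.07
CGC	5	0.36
CGA	29	2.07
CGG	7	0.5
AGU	42	0.88
AGC	10	0.21
AGA	68	1.42
AGG	34	0.71
GGU	51	0.88
GGC	33	0.57
GGA	95	1.63
GGG	54	0.93
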