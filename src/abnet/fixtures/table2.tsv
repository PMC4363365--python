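attribute	H	BBP	BC
Number of Nodes	121	121	121
Number of Links	1642	1932	1610
Diameter	7	6	7
Density	0.06	0.07	0.06
Node with more sociometric degree	24	115	111
Minimum Node number	2	2	2
Maximum Node number	39	45	32
Node number means	13.57	15.93	13.28
Standard deviation	7.23	9.56	6.68
Variance	52.26	91.35	44.59
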