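ID	Gene	dry	0h	12h
At3g63010	GID1b	8.32	8.58	8.28
At5g59310	LTP4	4.40	–	–
At4g02380	LEA5	2.34	–	–
At1g21630	EF hand family	1.65	2.77	2.95
At1g44575	NPQ4	0.89	–	–
At5g46050	PTR3	–	1.26	–
At5g54070	HSFA9	–	–	1.34
At4g09610	GASA2	–	–	1.29
At3g45970	EXPL1	–	–	1.01
At2g34740	A PP2C	–	–	0.97
At3g22490	A LEA	–	–	0.91
At5g45690	Unknown protein	–	–	0.83
At2g46240	BAG6	-2.13	-2.69	-3.19
At2g46250	Myosin heavy chain related	-1.31	-1.80	-3.39
At1g17430	α/β hydrolase fold family	–	-1.10	–
At5g01740	NTF2 family	–	-1.07	–
At5g48850	SDI1	–	-1.06	–
At5g58860	HORST	–	-1.00	–
At1g09200	Histone H3.1	–	-0.93	–
At1g22760	PAB3	–	-0.90	–
At5g56580	ANQ1/MKK6	–	-0.83	–
At1g56190	Phosphoglycerate kinase	–	-0.79	–
At5g15230	GASA4	–	–	-1.51
At5g07480	KUOX1	–	–	-1.28
At2g44800	Oxidoreductase	–	–	-1.13
At2g40880	CYSA	–	–	-0.77
At2g16060	AHb1/GLB1	–	–	-0.73
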