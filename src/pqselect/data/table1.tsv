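rank	peptide	abbreviation	selection_set
1	EAVSEILETSR	EAV	2
2	GLGASPGIGAGR	GLG	3
3	TIVVGSPNEK	TIV	1
4	NTIEGAEITPQK	NTI	1
5	VLGTPIEGIER	VLG	1
6	ALELENVLDR	ALE	1
7	AIETVDSAVR	AIE	1
8	IESIEEAIK	IES	2
9	GEIGEIPVVVEDR	GEI	3
10	GGGPALIGIGESDSNNR	GGG	3
11	AAAIVTDEGGR	AAA	2
12	VGNPAETLVSK	VGN	3
13	DLTSSIIQNENQHK	DLT	3
14	EIATAGTLEGR	EIA	1
15	GQDIAELEVR	GQD	1
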