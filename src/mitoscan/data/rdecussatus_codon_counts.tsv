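amino_acid	codon	count
Ala	GCG	29
Ala	GCA	44
Ala	GCT	85
Ala	GCC	30
Cys	TGT	94
Cys	TGC	30
Asp	GAT	54
Asp	GAC	28
Glu	GAG	87
Glu	GAA	58
Phe	TTT	269
Phe	TTC	78
Gly	GGG	131
Gly	GGA	61
Gly	GGT	98
Gly	GGC	36
His	CAT	37
His	CAC	23
Ile	ATT	165
Ile	ATC	40
Lys	AAG	61
Lys	AAA	87
Leu	TTG	122
Leu	TTA	210
Leu	CTG	43
Leu	CTA	70
Leu	CTT	75
Leu	CTC	20
Met	ATG	86
Met	ATA	155
Asn	AAT	76
Asn	AAC	39
Pro	CCG	16
Pro	CCA	36
Pro	CCT	58
Pro	CCC	24
Gln	CAG	25
Gln	CAA	32
Arg	CGG	23
Arg	CGA	21
Arg	CGT	25
Arg	CGC	6
Ser	AGG	69
Ser	AGA	69
Ser	AGT	55
Ser	AGC	23
Ser	TCG	18
Ser	TCA	33
Ser	TCT	76
Ser	TCC	22
Thr	ACG	21
Thr	ACA	30
Thr	ACT	57
Thr	ACC	16
Val	GTG	113
Val	GTA	121
Val	GTT	119
Val	GTC	23
Trp	TGG	58
Trp	TGA	49
Tyr	TAT	103
Tyr	TAC	47
STOP	TAG	34
STOP	TAA	25
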