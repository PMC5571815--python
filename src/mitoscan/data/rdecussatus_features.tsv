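# genome_id=Rdecussatus-F4
# genome_length=18995
name	type	start	stop	length	strand	anticodon	start_codon	stop_codon
cox1	coding	1	1716	1716	+		ATA	TAG
tRNA-Leu1	tRNA	1754	1815	62	+	TAG
nd1	coding	1822	2739	918	+		ATA	TAA
nd2	coding	2755	3774	1020	+		ATG	TAG
nd4l	coding	3780	4052	273	+		ATA	TAG
tRNA-Ile	tRNA	4125	4190	66	+	GAT
cox2	coding	4228	5499	1272	+		ATA	TAG
tRNA-Pro	tRNA	5553	5616	64	+	TGG
cytb	coding	5641	6864	1224	+		ATA	TAG
rrnL	rRNA	6865	8385	1521	+
atp6	coding	8386	9123	738	+		ATG	TAA
nd3	coding	9145	9552	408	+		ATG	TAA
nd5	coding	9631	11268	1638	+		ATG	TAG
atp8	coding	13379	13504	126	+		ATA	TAA
nd4	coding	13526	14865	1340	+		ATA	TA-
tRNA-His	tRNA	14866	14928	63	+	GTG
tRNA-Glu	tRNA	14929	14990	62	+	TTC
tRNA-Ser2	tRNA	14991	15052	62	+	TGA
tRNA-Tyr	tRNA	15081	15140	60	+	GTA
tRNA-Asp	tRNA	15218	15280	63	+	GTC
tRNA-Met	tRNA	15294	15358	65	+	CAT
nd6	coding	15380	15874	495	+		ATG	TAA
tRNA-Lys	tRNA	15897	15959	63	+	TTT
tRNA-Val	tRNA	15960	16021	62	+	TAC
tRNA-Phe	tRNA	16030	16092	63	+	GAA
tRNA-Trp	tRNA	16093	16155	63	+	TCA
tRNA-Arg	tRNA	16171	16232	62	+	TCG
tRNA-Leu2	tRNA	16233	16295	63	+	TAA
tRNA-Gly	tRNA	16297	16358	62	+	TCC
tRNA-Gln	tRNA	16359	16427	69	+	TTG
tRNA-Asn	tRNA	16435	16497	63	+	GTT
tRNA-Thr	tRNA	16498	16560	63	+	TGT
tRNA-Cys	tRNA	16565	16626	62	+	GCA
tRNA-Ala	tRNA	16632	16696	65	+	TGC
tRNA-Ser1	tRNA	16698	16764	67	+	TCT
cox3	coding	16765	17730	966	+		ATG	TAA
rrnS	rRNA	17731	18995	1265	+
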