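name	category	strand	start	end	anticodon	initiation_codon	termination_codon
trnI	tRNA	J	1	68	GAT
trnQ	tRNA	N	69	137	TTG
trnM	tRNA	J	137	205	CAT
ND2	PCG	J	206	1228		ATG	TAG
trnW	tRNA	J	1231	1297	TCA
trnC	tRNA	N	1290	1354	GCA
trnY	tRNA	N	1364	1429	GTA
COI	PCG	J	1431	2964		CCG	T
trnL(UUR)	tRNA	J	2965	3030	TAA
COII	PCG	J	3035	3718		ATG	TAA
trnD	tRNA	J	3722	3791	GTC
trnK	tRNA	J	3794	3864	CTT
ATP8	PCG	J	3882	4043		ATC	TAA
ATP6	PCG	J	4037	4714		ATG	TAA
COIII	PCG	J	4718	5509		ATG	TAA
trnG	tRNA	J	5513	5580	TCC
ND3	PCG	J	5581	5932		ATC	T
trnA	tRNA	J	5933	5998	TGC
trnR	tRNA	J	6002	6064	TCG
trnN	tRNA	J	6066	6130	GTT
trnS(AGN)	tRNA	J	6131	6197	GCT
trnE	tRNA	J	6199	6266	TTC
trnF	tRNA	N	6268	6333	GAA
ND5	PCG	N	6334	8050		ATT	T
trnH	tRNA	N	8066	8132	GTG
ND4	PCG	N	8133	9466		ATG	TA
ND4L	PCG	N	9460	9753		ATG	TAA
trnT	tRNA	J	9756	9823	TGT
trnP	tRNA	N	9824	9889	TGG
ND6	PCG	J	9892	10413		GTG	TAA
CytB	PCG	J	10417	11557		ATG	T
trnS(UCN)	tRNA	J	11558	11627	TGA
ND1	PCG	N	11654	12598		ATA	TAG
trnL(CUN)	tRNA	N	12602	12667	TAG
lrRNA	rRNA	N	12668	13987
trnV	tRNA	N	13988	14058	TAC
srRNA	rRNA	N	14059	14909
AT_rich	control	J	14910	15657
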