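name	category	strand	start	end	anticodon	initiation_codon	termination_codon
trnI	tRNA	J	1	68	GAT
trnQ	tRNA	N	69	137	TTG
trnM	tRNA	J	137	205	CAT
ND2	PCG	J	206	1228		ATG	TAG
trnW	tRNA	J	1231	1298	TCA
trnC	tRNA	N	1291	1355	GCA
trnY	tRNA	N	1364	1429	GTA
COI	PCG	J	1431	2964		CCG	T
trnL(UUR)	tRNA	J	2965	3030	TAA
COII	PCG	J	3036	3719		ATG	TAA
trnD	tRNA	J	3723	3793	GTC
trnK	tRNA	J	3796	3866	CTT
ATP8	PCG	J	3884	4045		ATC	TAA
ATP6	PCG	J	4039	4716		ATG	TAA
COIII	PCG	J	4720	5511		ATG	TAA
trnG	tRNA	J	5515	5581	TCC
ND3	PCG	J	5582	5935		ATC	TAG
trnA	tRNA	J	5934	5999	TGC
trnR	tRNA	J	6003	6066	TCG
trnN	tRNA	J	6069	6133	GTT
trnS(AGN)	tRNA	J	6134	6200	GCT
trnE	tRNA	J	6202	6268	TTC
trnF	tRNA	N	6270	6335	GAA
ND5	PCG	N	6336	8052		ATT	T
trnH	tRNA	N	8068	8135	GTG
ND4	PCG	N	8135	9469		ATG	TAG
ND4L	PCG	N	9463	9756		ATG	TAA
trnT	tRNA	J	9759	9826	TGT
trnP	tRNA	N	9827	9893	TGG
ND6	PCG	J	9896	10417		GTG	TAA
CytB	PCG	J	10421	11563		ATG	TAG
trnS(UCN)	tRNA	J	11562	11631	TGA
ND1	PCG	N	11658	12602		ATA	TAG
trnL(CUN)	tRNA	N	12606	12671	TAG
lrRNA	rRNA	N	12675	13988
trnV	tRNA	N	13991	14061	TAC
srRNA	rRNA	N	14062	14914
AT_rich	control	J	14915	15661
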