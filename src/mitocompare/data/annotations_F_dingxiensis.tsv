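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
COII	PCG	J	3036	3719		ATG	T
trnD	tRNA	J	3723	3793	GTC
trnK	tRNA	J	3796	3866	CTT
ATP8	PCG	J	3884	4045		ATC	TAA
ATP6	PCG	J	4039	4716		ATG	TAA
COIII	PCG	J	4721	5512		ATG	TAA
trnG	tRNA	J	5516	5582	TCC
ND3	PCG	J	5583	5936		ATC	TAG
trnA	tRNA	J	5935	6000	TGC
trnR	tRNA	J	6004	6067	TCG
trnN	tRNA	J	6070	6134	GTT
trnS(AGN)	tRNA	J	6135	6201	GCT
trnE	tRNA	J	6203	6269	TTC
trnF	tRNA	N	6271	6336	GAA
ND5	PCG	N	6337	8053		ATT	T
trnH	tRNA	N	8069	8136	GTG
ND4	PCG	N	8136	9470		ATG	TAG
ND4L	PCG	N	9464	9757		ATG	TAA
trnT	tRNA	J	9760	9827	TGT
trnP	tRNA	N	9828	9894	TGG
ND6	PCG	J	9897	10418		GTG	TAA
CytB	PCG	J	10422	11564		ATG	TAG
trnS(UCN)	tRNA	J	11563	11632	TGA
ND1	PCG	N	11658	12602		ATA	TAG
trnL(CUN)	tRNA	N	12607	12672	TAG
lrRNA	rRNA	N	12673	13993
trnV	tRNA	N	13994	14064	TAC
srRNA	rRNA	N	14065	14917
AT_rich	control	J	14918	15666
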