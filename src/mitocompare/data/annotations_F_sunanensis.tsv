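name	category	strand	start	end	anticodon	initiation_codon	termination_codon
trnI	tRNA	J	1	68	GAT
trnQ	tRNA	N	69	137	TTG
trnM	tRNA	J	137	205	CAT
ND2	PCG	J	206	1228		ATG	TAG
trnW	tRNA	J	1231	1297	TCA
trnC	tRNA	N	1290	1354	GCA
trnY	tRNA	N	1363	1428	GTA
COI	PCG	J	1430	2963		CCG	T
trnL(UUR)	tRNA	J	2964	3029	TAA
COII	PCG	J	3034	3717		ATG	TAA
trnD	tRNA	J	3721	3789	GTC
trnK	tRNA	J	3792	3862	CTT
ATP8	PCG	J	3880	4041		ATC	TAA
ATP6	PCG	J	4035	4712		ATG	TAA
COIII	PCG	J	4716	5507		ATG	TAA
trnG	tRNA	J	5511	5577	TCC
ND3	PCG	J	5578	5931		ATC	TAG
trnA	tRNA	J	5930	5995	TGC
trnR	tRNA	J	5996	6059	TCG
trnN	tRNA	J	6062	6126	GTT
trnS(AGN)	tRNA	J	6127	6193	GCT
trnE	tRNA	J	6195	6263	TTC
trnF	tRNA	N	6265	6329	GAA
ND5	PCG	N	6330	8046		ATT	T
trnH	tRNA	N	8062	8131	GTG
ND4	PCG	N	8132	9465		ATG	TA
ND4L	PCG	N	9459	9752		ATG	TAA
trnT	tRNA	J	9755	9822	TGT
trnP	tRNA	N	9823	9888	TGG
ND6	PCG	J	9891	10412		GTG	TAA
CytB	PCG	J	10416	11558		ATG	TAG
trnS(UCN)	tRNA	J	11557	11626	TGA
ND1	PCG	N	11653	12597		ATA	TAG
trnL(CUN)	tRNA	N	12601	12666	TAG
lrRNA	rRNA	N	12667	13986
trnV	tRNA	N	13987	14056	TAC
srRNA	rRNA	N	14057	14908
AT_rich	control	J	14909	15656
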