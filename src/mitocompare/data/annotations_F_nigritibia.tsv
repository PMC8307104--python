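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
ND3	PCG	J	5581	5934		ATC	TAG
trnA	tRNA	J	5933	5998	TGC
trnR	tRNA	J	6002	6065	TCG
trnN	tRNA	J	6067	6131	GTT
trnS(AGN)	tRNA	J	6132	6198	GCT
trnE	tRNA	J	6200	6267	TTC
trnF	tRNA	N	6269	6334	GAA
ND5	PCG	N	6335	8051		ATT	T
trnH	tRNA	N	8067	8133	GTG
ND4	PCG	N	8133	9467		ATG	TAG
ND4L	PCG	N	9461	9754		ATG	TAA
trnT	tRNA	J	9757	9826	TGT
trnP	tRNA	N	9827	9893	TGG
ND6	PCG	J	9896	10417		GTG	TAA
CytB	PCG	J	10421	11563		ATG	TAG
trnS(UCN)	tRNA	J	11562	11631	TGA
ND1	PCG	N	11658	12602		ATA	TAG
trnL(CUN)	tRNA	N	12606	12671	TAG
lrRNA	rRNA	N	12672	13991
trnV	tRNA	N	13992	14062	TAC
srRNA	rRNA	N	14063	14914
AT_rich	control	J	14915	15661
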