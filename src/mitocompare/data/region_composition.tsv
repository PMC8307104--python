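species	region	t_pct	c_pct	a_pct	g_pct	size	at_pct	at_skew	gc_skew
F_sunanensis	all_genes	30.6	16.1	42.3	11.0	15656	72.9	0.16	-0.19
F_sunanensis	rRNA_genes	29.7	16.9	43.2	10.3	2172	72.9	0.19	-0.24
F_sunanensis	tRNA_genes	31.1	16.5	38.7	13.6	1482	69.8	0.11	-0.10
F_sunanensis	AT_rich	37.7	9.4	45.6	7.4	748	83.3	0.09	-0.12
F_sunanensis	PCGs	41.4	14.0	31.2	13.5	11182	72.6	-0.14	-0.02
F_amplivertica	all_genes	30.3	16.4	42.1	11.2	15657	72.4	0.16	-0.19
F_amplivertica	rRNA_genes	29.7	16.9	43.2	10.3	2171	72.9	0.19	-0.24
F_amplivertica	tRNA_genes	31.4	16.5	38.4	13.8	1482	69.8	0.10	-0.09
F_amplivertica	AT_rich	36.9	9.9	46.5	6.7	748	83.4	0.12	-0.19
F_amplivertica	PCGs	41.1	14.3	30.7	13.9	11178	71.8	-0.14	-0.01
F_nigritibia	all_genes	30.3	16.5	42.0	11.3	15661	72.3	0.16	-0.19
F_nigritibia	rRNA_genes	29.7	16.8	43.1	10.4	2172	72.8	0.18	-0.24
F_nigritibia	tRNA_genes	31.7	16.2	38.4	13.7	1486	70.1	0.10	-0.08
F_nigritibia	AT_rich	37.8	10.4	44.4	7.4	747	82.2	0.08	-0.17
F_nigritibia	PCGs	40.9	14.4	30.9	13.9	11183	71.8	-0.14	-0.02
F_pamphagoides	all_genes	30.5	16.3	42.0	11.1	15661	72.5	0.16	-0.19
F_pamphagoides	rRNA_genes	30.0	17.2	42.1	10.7	2167	72.1	0.17	-0.23
F_pamphagoides	tRNA_genes	30.9	16.4	38.9	13.7	1485	69.8	0.11	-0.09
F_pamphagoides	AT_rich	36.1	10.2	46.2	7.5	747	82.3	0.12	-0.15
F_pamphagoides	PCGs	41.3	14.1	30.9	13.7	11183	72.2	-0.14	-0.01
F_dingxiensis	all_genes	30.6	16.3	42.0	11.0	15666	72.7	0.16	-0.19
F_dingxiensis	rRNA_genes	29.9	17.2	42.5	10.3	2175	72.4	0.17	-0.25
F_dingxiensis	tRNA_genes	30.9	16.6	38.7	13.8	1484	69.6	0.11	-0.09
F_dingxiensis	AT_rich	37.1	9.7	45.7	7.5	750	82.8	0.10	-0.13
F_dingxiensis	PCGs	41.3	14.0	31.0	13.6	11184	72.4	-0.14	-0.01
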