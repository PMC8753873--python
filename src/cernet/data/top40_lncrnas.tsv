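lncrna_id	gene_name	log2fc	fold_change	p_value
ENST00000487788	MEAF6	3.1242	8.7195	0.0000
ENST00000414790		2.8985	7.4566	0.0358
ENST00000497044	SHTN1	2.5531	5.8689	0.0290
ENST00000477686	MRPL20	2.4789	5.5747	0.0261
ENST00000506375	SLAIN2	2.0151	4.0421	0.0211
ENST00000450589	ZBTB37	1.9146	3.7701	0.0003
ENST00000595984	COPE	1.8744	3.6666	0.0249
ENST00000504082		1.7068	3.2644	0.0198
ENST00000506853	AGA	1.6727	3.1882	0.0170
ENST00000483937	MAPKAP1	1.6650	3.1712	0.0017
ENST00000483900	AHCTF1	1.6037	3.0394	0.0486
ENST00000474105	IGF2BP3	1.5885	3.0074	0.0262
ENST00000417089		1.4379	2.7092	0.0031
ENST00000494757	WIPF2	1.4303	2.6950	0.0122
ENST00000608018		1.3741	2.5920	0.0016
ENST00000548674	ARHGAP9	1.3432	2.5372	0.0019
ENST00000434411	SEC14L1	1.3218	2.4998	0.0455
ENST00000608072	BACH1	1.3184	2.4939	0.0254
ENST00000573166	HIC1	1.2892	2.4439	0.0000
ENST00000508708	CSNK1G3	1.2802	2.4287	0.0385
ENST00000442037		-2.9296	0.131	0.0064
ENST00000472229	MRPS18B	-2.7050	0.1533	0.0426
ENST00000521414	NDRG1	-2.6551	0.1587	0.0076
ENST00000475828	MEAF6	-1.9648	0.2561	0.0000
ENST00000498494	SELENBP1	-1.9296	0.2625	0.0242
ENST00000571618	TBCD	-1.7755	0.2921	0.0391
ENST00000509980	EXOSC9	-1.7089	0.3059	0.0094
ENST00000626681	BACH1	-1.5875	0.3327	0.0430
ENST00000469145	HDGF	-1.3972	0.3796	0.0148
ENST00000527751	PRR5L	-1.1769	0.4422	0.0270
ENST00000526095	KCNQ1	-1.1363	0.4549	0.0021
ENST00000611525		-1.1224	0.4593	0.0010
ENST00000474372	UBAP2	-1.0733	0.4752	0.0484
ENST00000531542	AMBRA1	-1.0705	0.4761	0.0168
ENST00000480603	PPIA	-1.0677	0.4770	0.0011
ENST00000506641	CLPTM1L	-1.0613	0.4791	0.0259
ENST00000480181	CLIC3	-1.0504	0.4828	0.0009
ENST00000495212	HDGF	-1.0479	0.4836	0.0042
ENST00000316543	AACS	-1.0453	0.4845	0.0105
ENST00000623297		-1.0229	0.4921	0.0142
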