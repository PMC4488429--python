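name	start	end	strand	type
tRNA-Phe	538	609	H	tRNA
rrnS	610	1556	H	rRNA
tRNA-Val	1557	1625	H	tRNA
rrnL	1626	3184	H	rRNA
tRNA-Leu(L2)	3185	3259	H	tRNA
ND1	3262	4216	H	PCG
tRNA-Ile	4217	4285	H	tRNA
tRNA-Gln	4283	4354	L	tRNA
tRNA-Met	4356	4423	H	tRNA
ND2	4424	5465	H	PCG
tRNA-Trp	5466	5532	H	tRNA
tRNA-Ala	5540	5608	L	tRNA
tRNA-Asn	5610	5682	L	tRNA
tRNA-Cys	5715	5783	L	tRNA
tRNA-Tyr	5784	5847	L	tRNA
COX1	5852	7420	H	PCG
tRNA-Ser(S2)	7393	7461	L	tRNA
tRNA-Asp	7465	7532	H	tRNA
COX2	7534	8217	H	PCG
tRNA-Lys	8291	8353	H	tRNA
ATP8	8355	8561	H	PCG
ATP6	8516	9196	H	PCG
COX3	9196	9979	H	PCG
tRNA-Gly	9980	10047	H	tRNA
ND3	10048	10393	H	PCG
tRNA-Arg	10394	10458	H	tRNA
ND4L	10459	10755	H	PCG
ND4	10749	12126	H	PCG
tRNA-His	12127	12195	H	tRNA
tRNA-Ser(S1)	12196	12254	H	tRNA
tRNA-Leu(L1)	12255	12325	H	tRNA
ND5	12326	14137	H	PCG
ND6	14138	14665	L	PCG
tRNA-Glu	14666	14734	L	tRNA
CYTB	14739	15879	H	PCG
tRNA-Thr	15880	15943	H	tRNA
tRNA-Pro	15945	16012	L	tRNA
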