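# rCRS (NC_012920.1) locus annotation, 1-based inclusive coordinates on the
# circular 16,569-bp mitochondrial genome. A row with start > end wraps the
# origin (D-loop). Positions claimed by two loci, or by none, resolve to the
# complement macro region "Other".
locus	start	end	macro	strand
D-loop	16024	576	D-loop	H
MT-TF	577	647	tRNA	H
MT-RNR1	648	1601	rRNA	H
MT-TV	1602	1670	tRNA	H
MT-RNR2	1671	3229	rRNA	H
MT-TL1	3230	3304	tRNA	H
MT-ND1	3307	4262	ComplexI	H
MT-TI	4263	4331	tRNA	H
MT-TQ	4329	4400	tRNA	L
MT-TM	4402	4469	tRNA	H
MT-ND2	4470	5511	ComplexI	H
MT-TW	5512	5579	tRNA	H
MT-TA	5587	5655	tRNA	L
MT-TN	5657	5729	tRNA	L
MT-TC	5761	5826	tRNA	L
MT-TY	5826	5891	tRNA	L
MT-CO1	5904	7445	ComplexIV	H
MT-TS1	7446	7514	tRNA	L
MT-TD	7518	7585	tRNA	H
MT-CO2	7586	8269	ComplexIV	H
MT-TK	8295	8364	tRNA	H
MT-ATP8	8366	8572	ComplexV	H
MT-ATP6	8527	9207	ComplexV	H
MT-CO3	9207	9990	ComplexIV	H
MT-TG	9991	10058	tRNA	H
MT-ND3	10059	10404	ComplexI	H
MT-TR	10405	10469	tRNA	H
MT-ND4L	10470	10766	ComplexI	H
MT-ND4	10760	12137	ComplexI	H
MT-TH	12138	12206	tRNA	H
MT-TS2	12207	12265	tRNA	H
MT-TL2	12266	12336	tRNA	H
MT-ND5	12337	14148	ComplexI	H
MT-ND6	14149	14673	ComplexI	L
MT-TE	14674	14742	tRNA	L
MT-CYB	14747	15887	ComplexIII	H
MT-TT	15888	15953	tRNA	H
MT-TP	15956	16023	tRNA	L
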