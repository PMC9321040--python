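Gene/Region	Code	Coordinates	Strand	Size (bp)	Anticodon	Start	Stop	IGN
COI	-	1–1540	J	1540	-	ATT	T--	−8
tRNA-Leu2	L2	1541–1606	J	66	TAA	-	-	0
COII	-	1607–2290	J	684	-	ATT	TAA	0
tRNA-Lys	K	2307–2378	J	72	CTT	-	-	16
tRNA-Asp	D	2378–2448	J	66	GTC	-	-	−1
ATP8	-	2444–2599	J	156	-	ATT	TAG	0
ATP6	-	2596–3266	J	671	-	ATA	TA-	−4
COIII	-	3267–4055	J	789	-	ATG	TAA	0
tRNA-Gly	G	4076–4141	J	66	TCC	-	-	20
ND3	-	4142–4495	J	354	-	ATA	TAA	0
tRNA-Ala	A	4498–4562	J	65	TGC	-	-	2
tRNA-Arg	R	4563–4631	J	69	TCG	-	-	0
tRNA-Asn	N	4629–4691	J	63	GTT	-	-	−3
tRNA-Ser1	S1	4692–4757	J	66	AGA	-	-	0
tRNA-Glu	E	4758–4821	J	64	TTC	-	-	0
tRNA-Phe	F	4831–4897	N	67	GAA	-	-	9
ND5	-	4901–6619	N	1719	-	ATT	TAA	3
tRNA-His	H	6620–6684	N	65	GTG	-	-	0
ND4	-	6687–8018	N	1332	-	ATG	TAG	2
ND4L	-	8012–8296	N	285	-	ATG	TAA	−7
tRNA-Thr	T	8299–8366	J	68	TGT	-	-	2
tRNA-Pro	P	8367–8432	N	66	TGG	-	-	0
ND6	-	8433–8935	J	503	-	ATA	TA-	0
CYTB	-	8936–10075	J	1140	-	ATG	TAA	0
tRNA-Ser2	S2	10,079–10,147	J	69	TGA	-	-	3
ND1	-	10,218–11,168	N	951	-	TTG	TAG	70
tRNA-Leu1	L1	11,169–11,235	N	67	TAG	-	-	0
16S rRNA	-	11,236–12,534	N	1299	-	-	-	0
tRNA-Val	-	12,535–12,599	N	65	TAC	-	-	0
12S rRNA	-	12,600–13,378	N	779	-	-	-	0
AT-rich region	-	13,380–14,151	-	772	-	-	-	0
tRNA-Ile	I	n.d.	n.d.	n.d.	n.d.	-	-	n.d.
tRNA-Gln	Q	14,154–14,224	N	71	TTG	-	-	0
tRNA-Met	M	14,222–14,291	J	70	CAT	-	-	−3
ND2	-	14,292–15,305	J	1014	-	ATG	TAA	0
tRNA-Trp	W	15,308–15,373	J	66	TCA	-	-	2
tRNA-Cys	C	15,375–15,436	N	62	GCA	-	-	1
tRNA-Tyr	Y	15,442–15,497	N	64	GTA	-	-	5
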