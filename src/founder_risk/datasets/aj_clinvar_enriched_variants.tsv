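#variant	hgvs	gene	enrichment_odds_ratio	study_af	max_ref_af
16:3293310:A:G	p.Val726Ala	MEFV	26.08	0.0416	0.0017
5:150723155:C:A	p.Gly87Val	SLC36A2	3.51	0.0414	0.0122
1:155205634:T:C	p.Asn409Ser	GBA	11.16	0.0296	0.0027
4:187201412:T:C	p.Phe301Leu	F11	47.17	0.0273	0.0006
13:20763553:CA:C	p.Leu56Argfs	GJB2	39.19	0.0199	0.0005
4:187195347:G:T	p.Glu135Ter	F11	28.20	0.0195	0.0007
12:14421038:G:A	p.Arg49Cys	PRB3	16.12	0.0189	0.0012
9:111662096:A:G	c.2204+6T>C	IKBKAP	45.22	0.0168	0.0004
15:72638920:G:GGATA	p.Tyr427IlefsTer5	HEXA	19.14	0.0122	0.00064
1:125848678:C:T	p.Arg4192His	USH2A	13.63	0.0106	0.0008
22:29091207:G:A	p.Ser428Phe	CHEX2	50.06	0.0103	0.0002
10:99371368:TGAG:T	p.Glu315del	HOGA1	29.28	0.0101	0.0003
7:117282620:G:A	p.Trp1282Ter	CFTR	23.64	0.0085	0.0004
11:17418602:C:T	c.3992-9G>A	ABCC8	40.62	0.0076	0.0002
17:3402294:A:C	p.Glu285Ala	ASPA	40.36	0.0076	0.0002
2:98986540:G:A	c.101+1G>A	CNGA3	26.11	0.0074	0.0003
13:32914437:GT:G	p.Ser1982Argfs	BRCA2	27.57	0.0069	0.0003
9:97934315:T:A	c.456+4A>T	FANCC	42.75	0.0069	0.0002
9:108382330:G:GA	p.Phe390Ilefs	FKTN	32.62	0.0067	0.0002
12:40734202:G:A	p.Gly2019Ser	LRRK2	20.64	0.0064	0.0003
17:41055964:C:T	p.Arg83Cys	G6PC	11.04	0.0062	0.0006
1:26764719:A:G	p.Lys42Glu	DHDDS	64.83	0.0051	0.0001
3:150690352:A:C	p.Asn48Lys	CLRN1	46.26	0.0051	0.0001
12:49312533:GTA:G	p.Ile293Profs	CCDC65	25.75	0.0048	0.0002
6:80878662:G:C	p.Arg183Pro	BCKDHB	29.42	0.0046	0.0002
10:56077147:G:A	p.Arg245Ter	PCDH15	26.58	0.0046	0.0002
7:107555951:G:T	p.Gly229Cys	DLD	26.55	0.0046	0.0002
15:72638575:C:G	c.1421+1G>C	HEXA	52.65	0.0044	0.0001
15:72105913:G:A	p.Arg311Gln	NR2E3	9.86	0.0042	0.0004
5:178699927:G:A	p.Gln225Ter	ADAMTS2	129.41	0.0041	0.0000
16:50745656:G:A	p.Ala612Thr	NOD2	12.48	0.0039	0.0003
11:6415434:G:T	p.Arg498Leu	SMPD1	41.53	0.0039	0.0001
11:61161437:G:T	p.Arg73Leu	THEM216	27.77	0.0039	0.0001
1:53676583:CAG:C	p.Lys414ThrfsTer7	CPT2	78.34	0.0037	0.0000
1:53676688:T:C	p.Phe448Leu	CPT2	78.35	0.0037	0.0000
3:172737276:C:T	p.Arg283Gln	SPATA16	9.79	0.0037	0.0004
11:86017416:G:C	p.Val54Leu	C11orf73	47.03	0.0037	0.0001
8:77896070:G:A	p.Arg119Ter	PEX2	20.03	0.0034	0.0002
11:118951899:T:G	p.Cys845Gly	VPS11	190.98	0.0030	0.0000
6:80203353:G:A	p.Gln279Ter	LCA5	29.25	0.0028	0.0001
19:7591645:A:G	c.406-2A>G	MCOLN1	21.93	0.0028	0.0001
16:56530894:C:G	p.Arg632Pro	BBS2	29.37	0.0028	0.0001
17:41276044:ACT:A	p.Glu23Valfs	BRCA1	10.04	0.0025	0.0003
4:100543913:G:T	p.Gly865Ter	MTTP	40.38	0.0025	0.0001
2:99013302:G:A	p.Gly557Arg	CNGA3	29.36	0.0023	0.0001
7:107557794:G:A	p.Glu375Lys	DLD	26.44	0.0021	0.0001
17:41209079:T:TG	p.Gln1756Profs	BRCA1	8.80	0.0021	0.0002
10:99371292:G:T	p.Gly287Val	HOGA1	22.01	0.0021	0.0001
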