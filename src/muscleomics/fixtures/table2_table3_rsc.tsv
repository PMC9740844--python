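accession	gene	rsc
Q9NQX4	MYO5C	4.51
Q9UNM6	PSMD13	3.72
P02774	GC	3.72
Q9NX40	OCIAD1	3.43
P04632	CAPNS1	3.43
P50991	CCT4	3.43
Q8NBN7	RDH13	3.43
Q5HYK3	COQ5	3.43
O75891	ALDH1L1	3.43
P11532	DMD	3.43
O95182	NDUFA7	3.07
Q9UFN0	NIPSNAP3A	3.07
P55039	DRG2	3.07
Q9NUJ1	ABHD10	3.07
Q9H9P8	L2HGDH	3.07
O43464	HTRA2	3.07
Q15181	PPA1	3.07
O15399	GRIN2D	3.07
O60229	KALRN	3.07
Q00G26	PLIN5	3.07
Q13203	MYBPH	3.07
Q8N3L3	TXLNB	2.58
P49773	HINT1	2.58
P21964	COMT	2.58
P61353	RPL27	2.58
Q15404	RSU1	2.58
Q9UPY8	MAPRE3	2.58
Q8WUY1	THEM6	2.58
O96008	TOMM40	2.58
Q9NQ50	MRPL40	2.58
O00743	PPP6C	2.58
P15880	RPS2	2.58
Q5T3I0	GPATCH4	2.58
Q7Z3D6	DGLUCY	2.58
P54868	HMGCS2	2.58
Q13555	CAMK2G	2.58
Q969N2	PIGT	2.58
Q92523	CPT1B	2.58
Q13554	CAMK2B	2.58
Q96AQ6	PBXIP1	2.58
P43243	MATR3	2.58
P07384	CAPN1	2.58
Q02641	CACNB1	2.58
Q9NVI1	FANCI	2.58
O14936	CASK	2.58
P39059	COL15A1	2.58
Q92900	UPF1	2.58
Q9Y490	TLN1	2.58
Q8NEZ4	KMT2C	2.58
Q9NZJ6	COQ3	2.38
O94874	UFL1	2.38
Q5T440	IBA57	2.38
Q15642	TRIP10	2.38
Q16795	NDUFA9	2.2
Q9H2U2	PPA2	2.13
Q9H799	CPLANE1	2.13
P02675	FGB	2.13
P40123	CAP2	2.13
P42765	ACAA2	2.1
Q9HC38	GLOD4	1.85
P61019	RAB2A	1.85
P35270	SPR	1.85
P67809	YBX1	1.85
Q9H6K4	OPA3	1.85
Q15124	PGM5	1.85
Q02224	CENPE	1.85
P45954	ACADSB	1.85
Q9H0P0	NT5C3A	1.76
P10809	HSPD1	1.76
P56134	ATP5J2	1.64
O75150	RNF40	1.64
Q15746	MYLK	1.64
P42704	LRPPRC	1.64
P53597	SUCLG1	1.57
P62701	RPS4X	1.54
Q0VFZ6	CCDC173	1.48
P46778	RPL21	1.48
P07741	APRT	1.48
Q02338	BDH1	1.48
O75915	ARL6IP5	1.48
P62081	RPS7	1.48
Q13557	CAMK2D	1.48
Q9Y512	SAMM50	1.48
Q00839	HNRNPU	1.48
P07919	UQCRH	1.48
P62899	RPL31	1.48
Q99733	NAP1L4	1.48
Q9UKU7	ACAD8	1.48
P15088	CPA3	1.48
Q96A26	FAM162A	1.48
Q15555	MAPRE2	1.48
P21817	RYR1	1.44
P51911	CNN1	-4.78
Q01995	TAGLN	-4.6
P02790	HPX	-3.83
Q14847	LASP1	-3.65
Q9UNZ2	NSFL1C	-3.65
P13798	APEH	-3.44
P48147	PREP	-3.44
P02679	FGG	-3.2
P62280	RPS11	-3.2
Q2TBA0	KLHL40	-3.2
Q9Y6B6	SAR1B	-2.91
Q15370	TCEB2	-2.91
Q969G5	PRKCDBP	-2.91
P02743	APCS	-2.91
P21980	TGM2	-2.91
Q13526	PIN1	-2.91
P0CW22	RPS17L	-2.91
O15145	ARPC3	-2.91
Q13561	DCTN2	-2.91
P31153	MAT2A	-2.91
P22061	PCMT1	-2.84
P49189	ALDH9A1	-2.68
P56556	NDUFA6	-2.55
O14602	EIF1AY	-2.55
P31942	HNRNPH3	-2.55
P30566	ADSL	-2.55
Q9C0G0	ZNF407	-2.55
Q8IUG5	MYO18B	-2.55
Q9GZZ1	NAA50	-2.55
Q00765	REEP5	-2.55
P62491	RAB11A	-2.55
P62195	PSMC5	-2.55
P01011	SERPINA3	-2.55
Q16853	AOC3	-2.55
P36776	LONP1	-2.55
Q7L7X3	TAOK1	-2.55
P78527	PRKDC	-2.55
P51884	LUM	-2.29
P61026	RAB10	-2.24
P20774	OGN	-2.19
O94760	DDAH1	-2.06
P38646	HSPA9	-2.06
P20618	PSMB1	-2.06
P61254	RPL26	-2.06
Q15185	PTGES3	-2.06
P07203	GPX1	-2.06
Q96IU4	ABHD14B	-2.06
Q9H8H3	METTL7A	-2.06
P55042	RRAD	-2.06
P50454	SERPINH1	-2.06
Q99807	COQ7	-2.06
P54619	PRKAG1	-2.06
O43765	SGTA	-2.06
Q9BUB7	TMEM70	-2.06
Q9Y3B7	MRPL11	-2.06
P27169	PON1	-2.06
Q00059	TFAM	-2.06
Q99536	VAT1	-2.06
Q15366	PCBP2	-2.06
P43686	PSMC4	-2.06
P51888	PRELP	-2.06
Q9Y230	RUVBL2	-2.06
P16930	FAH	-2.06
P48637	GSS	-2.06
P31948	STIP1	-2.06
Q8NBS9	TXNDC5	-2.06
O00148	DDX39A	-2.06
Q9HCC0	MCCC2	-2.06
Q9NZN4	EHD2	-2.06
P23246	SFPQ	-2.06
Q9NUB1	ACSS1	-2.06
Q9P1V8	SAMD15	-2.06
P00747	PLG	-2.06
O14795	UNC13B	-2.06
Q702N8	XIRP1	-2.06
Q8IWN7	RP1L1	-2.06
Q16787	LAMA3	-2.06
P07585	DCN	-1.94
P21291	CSRP1	-1.89
P20073	ANXA7	-1.89
P62993	GRB2	-1.86
P52895	AKR1C2	-1.79
O43488	AKR7A2	-1.69
Q9BXI3	NT5C1A	-1.67
P61106	RAB14	-1.61
P62277	RPS13	-1.61
Q15084	PDIA6	-1.61
P16083	NQO2	-1.61
P47985	UQCRFS1	-1.53
P02545	LMNA	-1.53
P24844	MYL9	-1.51
P09382	LGALS1	-1.51
P28070	PSMB4	-1.51
P62269	RPS18	-1.51
P14543	NID1	-1.51
P13716	ALAD	-1.46
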