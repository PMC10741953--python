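chr1	39559000	39560200	PPIEL	germline	maternal
chr1	68046500	68047500	DIRAS3:TSS	germline	maternal
chr1	68050300	68051300	DIRAS3:Ex2	germline	maternal
chr2	206249000	206251000	ZDBF2	germline	paternal
chr2	206230000	206231500	GPR1-AS	germline	maternal
chr4	88696000	88697000	NAP1L5	germline	maternal
chr5	136079000	136080000	VTRNA2	germline	maternal
chr6	3848900	3850000	FAM50B	germline	maternal
chr6	144006000	144008000	PLAGL1:alt-TSS	germline	maternal
chr6	160005000	160006500	IGF2R	germline	maternal
chr7	50781000	50783000	GRB10:alt-TSS	germline	maternal
chr7	130490000	130494000	MEST	germline	maternal
chr7	130341000	130342000	CPA4	germline	maternal
chr7	155470000	155471500	HTR5A:TSS	germline	maternal
chr8	37604500	37606000	ERLIN2:Int6	germline	maternal
chr8	140088000	140090000	PEG13	germline	maternal
chr8	140098000	140099000	TRAPPC9	germline	maternal
chr9	3824500	3825500	GLIS3	germline	maternal
chr10	119815000	119816500	INPP5F	germline	maternal
chr11	1999745	2003509	H19/IGF2	germline	paternal
chr11	2133800	2134800	IGF2:alt-TSS	germline	paternal
chr11	2141000	2142500	IGF2:Ex9	secondary	paternal
chr11	2698500	2701000	KCNQ1OT1	germline	maternal
chr13	48317500	48319500	RB1	germline	maternal
chr14	100824000	100827000	MEG3:TSS	germline	paternal
chr14	100810000	100812000	MEG3	secondary	paternal
chr14	100905000	100906500	MEG8	secondary	paternal
chr15	23565000	23566500	MKRN3:TSS	secondary	paternal
chr15	23647000	23648500	MAGEL2:TSS	secondary	paternal
chr15	23686300	23687500	NDN:TSS	secondary	paternal
chr15	24823000	24824500	SNRPN:alt-TSS	secondary	paternal
chr15	24954500	24956500	SNRPN:Int1	secondary	paternal
chr15	24972000	24973500	SNRPN:Int2	secondary	paternal
chr15	25200000	25201500	SNURF:TSS	germline	maternal
chr15	98875000	98876500	IGF1R:Int2	germline	maternal
chr15	92700000	92701000	RGMA	germline	maternal
chr16	3482000	3483000	ZNF597_1	germline	maternal
chr16	3492500	3493500	ZNF597:TSS	secondary	maternal
chr19	53537500	53539000	ZNF331_1	germline	maternal
chr19	53552000	53553500	ZNF331_2	germline	maternal
chr19	56837000	56839500	PEG3	germline	maternal
chr20	31546500	31548000	MCTS2P	germline	maternal
chr20	37519000	37521000	BLCAP/NNAT	germline	maternal
chr20	37522500	37523500	NNAT:TSS	secondary	maternal
chr20	43514500	43516500	L3MBTL1	germline	maternal
chr20	58830000	58832000	NESP	secondary	maternal
chr20	58838500	58840500	GNAS-AS1	germline	maternal
chr20	58851500	58853500	GNAS-XL	germline	maternal
chr20	58888500	58890500	GNAS A/B	germline	maternal
chr21	39385500	39387000	WRB	germline	maternal
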