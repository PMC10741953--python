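probe_id	chrom	pos	snp_overlap	sex_chrom
cgIDMR0001	chr1	39559150	False	False
cgIDMR0002	chr1	39559300	False	False
cgIDMR0003	chr1	39559450	False	False
cgIDMR0004	chr1	39559600	False	False
cgIDMR0005	chr1	68046650	False	False
cgIDMR0006	chr1	68046800	False	False
cgIDMR0007	chr1	68046950	False	False
cgIDMR0008	chr1	68047100	False	False
cgIDMR0009	chr1	68050450	False	False
cgIDMR0010	chr1	68050600	False	False
cgIDMR0011	chr1	68050750	False	False
cgIDMR0012	chr1	68050900	False	False
cgIDMR0013	chr1	68051050	False	False
cgIDMR0014	chr2	206249150	False	False
cgIDMR0015	chr2	206249300	False	False
cgIDMR0016	chr2	206249450	False	False
cgIDMR0017	chr2	206249600	False	False
cgIDMR0018	chr2	206230150	False	False
cgIDMR0019	chr2	206230300	False	False
cgIDMR0020	chr2	206230450	False	False
cgIDMR0021	chr2	206230600	False	False
cgIDMR0022	chr4	88696150	False	False
cgIDMR0023	chr4	88696300	False	False
cgIDMR0024	chr5	136079150	False	False
cgIDMR0025	chr5	136079300	False	False
cgIDMR0026	chr5	136079450	False	False
cgIDMR0027	chr5	136079600	False	False
cgIDMR0028	chr6	3849050	False	False
cgIDMR0029	chr6	3849200	False	False
cgIDMR0030	chr6	3849350	False	False
cgIDMR0031	chr6	3849500	False	False
cgIDMR0032	chr6	144006150	False	False
cgIDMR0033	chr6	144006300	False	False
cgIDMR0034	chr6	144006450	False	False
cgIDMR0035	chr6	144006600	False	False
cgIDMR0036	chr6	144006750	False	False
cgIDMR0037	chr6	160005150	False	False
cgIDMR0038	chr6	160005300	False	False
cgIDMR0039	chr7	50781150	False	False
cgIDMR0040	chr7	50781300	False	False
cgIDMR0041	chr7	50781450	False	False
cgIDMR0042	chr7	50781600	False	False
cgIDMR0043	chr7	50781750	False	False
cgIDMR0044	chr7	130490150	False	False
cgIDMR0045	chr7	130490300	False	False
cgIDMR0046	chr7	130490450	False	False
cgIDMR0047	chr7	130490600	False	False
cgIDMR0048	chr7	130490750	False	False
cgIDMR0049	chr7	130490900	False	False
cgIDMR0050	chr7	130341150	False	False
cgIDMR0051	chr7	130341300	False	False
cgIDMR0052	chr7	155470150	False	False
cgIDMR0053	chr7	155470300	False	False
cgIDMR0054	chr7	155470450	False	False
cgIDMR0055	chr7	155470600	False	False
cgIDMR0056	chr8	37604650	False	False
cgIDMR0057	chr8	37604800	False	False
cgIDMR0058	chr8	37604950	False	False
cgIDMR0059	chr8	37605100	False	False
cgIDMR0060	chr8	140088150	False	False
cgIDMR0061	chr8	140088300	False	False
cgIDMR0062	chr8	140088450	False	False
cgIDMR0063	chr8	140088600	False	False
cgIDMR0064	chr8	140098150	False	False
cgIDMR0065	chr8	140098300	False	False
cgIDMR0066	chr9	3824650	False	False
cgIDMR0067	chr10	119815150	False	False
cgIDMR0068	chr10	119815300	False	False
cgIDMR0069	chr10	119815450	False	False
cgIDMR0070	chr11	1999895	False	False
cgIDMR0071	chr11	2000045	False	False
cgIDMR0072	chr11	2000195	False	False
cgIDMR0073	chr11	2000345	False	False
cgIDMR0074	chr11	2000495	False	False
cgIDMR0075	chr11	2000645	False	False
cgIDMR0076	chr11	2000795	False	False
cgIDMR0077	chr11	2000945	False	False
cgIDMR0078	chr11	2133950	False	False
cgIDMR0079	chr11	2141150	False	False
cgIDMR0080	chr11	2141300	False	False
cgIDMR0081	chr11	2141450	False	False
cgIDMR0082	chr11	2141600	False	False
cgIDMR0083	chr11	2698650	False	False
cgIDMR0084	chr11	2698800	False	False
cgIDMR0085	chr11	2698950	False	False
cgIDMR0086	chr11	2699100	False	False
cgIDMR0087	chr11	2699250	False	False
cgIDMR0088	chr11	2699400	False	False
cgIDMR0089	chr13	48317650	False	False
cgIDMR0090	chr13	48317800	False	False
cgIDMR0091	chr13	48317950	False	False
cgIDMR0092	chr13	48318100	False	False
cgIDMR0093	chr14	100824150	False	False
cgIDMR0094	chr14	100824300	False	False
cgIDMR0095	chr14	100824450	False	False
cgIDMR0096	chr14	100824600	False	False
cgIDMR0097	chr14	100824750	False	False
cgIDMR0098	chr14	100824900	False	False
cgIDMR0099	chr14	100810150	False	False
cgIDMR0100	chr14	100810300	False	False
cgIDMR0101	chr14	100810450	False	False
cgIDMR0102	chr14	100810600	False	False
cgIDMR0103	chr14	100905150	False	False
cgIDMR0104	chr14	100905300	False	False
cgIDMR0105	chr14	100905450	False	False
cgIDMR0106	chr15	23565150	False	False
cgIDMR0107	chr15	23565300	False	False
cgIDMR0108	chr15	23565450	False	False
cgIDMR0109	chr15	23565600	False	False
cgIDMR0110	chr15	23647150	False	False
cgIDMR0111	chr15	23647300	False	False
cgIDMR0112	chr15	23647450	False	False
cgIDMR0113	chr15	23686450	False	False
cgIDMR0114	chr15	23686600	False	False
cgIDMR0115	chr15	23686750	False	False
cgIDMR0116	chr15	24823150	False	False
cgIDMR0117	chr15	24823300	False	False
cgIDMR0118	chr15	24823450	False	False
cgIDMR0119	chr15	24954650	False	False
cgIDMR0120	chr15	24954800	False	False
cgIDMR0121	chr15	24954950	False	False
cgIDMR0122	chr15	24955100	False	False
cgIDMR0123	chr15	24972150	False	False
cgIDMR0124	chr15	24972300	False	False
cgIDMR0125	chr15	24972450	False	False
cgIDMR0126	chr15	24972600	False	False
cgIDMR0127	chr15	25200150	False	False
cgIDMR0128	chr15	25200300	False	False
cgIDMR0129	chr15	25200450	False	False
cgIDMR0130	chr15	25200600	False	False
cgIDMR0131	chr15	25200750	False	False
cgIDMR0132	chr15	98875150	False	False
cgIDMR0133	chr15	98875300	False	False
cgIDMR0134	chr15	98875450	False	False
cgIDMR0135	chr15	92700150	False	False
cgIDMR0136	chr16	3482150	False	False
cgIDMR0137	chr16	3482300	False	False
cgIDMR0138	chr16	3492650	False	False
cgIDMR0139	chr16	3492800	False	False
cgIDMR0140	chr16	3492950	False	False
cgIDMR0141	chr19	53537650	False	False
cgIDMR0142	chr19	53537800	False	False
cgIDMR0143	chr19	53537950	False	False
cgIDMR0144	chr19	53552150	False	False
cgIDMR0145	chr19	53552300	False	False
cgIDMR0146	chr19	53552450	False	False
cgIDMR0147	chr19	53552600	False	False
cgIDMR0148	chr19	56837150	False	False
cgIDMR0149	chr19	56837300	False	False
cgIDMR0150	chr19	56837450	False	False
cgIDMR0151	chr19	56837600	False	False
cgIDMR0152	chr19	56837750	False	False
cgIDMR0153	chr19	56837900	False	False
cgIDMR0154	chr20	31546650	False	False
cgIDMR0155	chr20	31546800	False	False
cgIDMR0156	chr20	31546950	False	False
cgIDMR0157	chr20	31547100	False	False
cgIDMR0158	chr20	37519150	False	False
cgIDMR0159	chr20	37519300	False	False
cgIDMR0160	chr20	37519450	False	False
cgIDMR0161	chr20	37519600	False	False
cgIDMR0162	chr20	37519750	False	False
cgIDMR0163	chr20	37522650	False	False
cgIDMR0164	chr20	37522800	False	False
cgIDMR0165	chr20	37522950	False	False
cgIDMR0166	chr20	43514650	False	False
cgIDMR0167	chr20	43514800	False	False
cgIDMR0168	chr20	43514950	False	False
cgIDMR0169	chr20	43515100	False	False
cgIDMR0170	chr20	58830150	False	False
cgIDMR0171	chr20	58830300	False	False
cgIDMR0172	chr20	58830450	False	False
cgIDMR0173	chr20	58838650	False	False
cgIDMR0174	chr20	58838800	False	False
cgIDMR0175	chr20	58838950	False	False
cgIDMR0176	chr20	58839100	False	False
cgIDMR0177	chr20	58851650	False	False
cgIDMR0178	chr20	58851800	False	False
cgIDMR0179	chr20	58851950	False	False
cgIDMR0180	chr20	58852100	False	False
cgIDMR0181	chr20	58888650	False	False
cgIDMR0182	chr20	58888800	False	False
cgIDMR0183	chr20	58888950	False	False
cgIDMR0184	chr20	58889100	False	False
cgIDMR0185	chr20	58889250	False	False
cgIDMR0186	chr21	39385650	False	False
cgIDMR0187	chr21	39385800	False	False
cgIDMR0188	chr21	39385950	False	False
cgIDMR0189	chr21	39386100	False	False
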