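genus	species	marker	ra	sv
Dermoloma	sp. 8	ITS1	1002	1
Dermoloma	sp. 8	ITS2	1031	1
Dermoloma	sp. 8	rpb2	2682	1
Dermoloma	sp. 8	ef1a	496	2
Dermoloma	bellerianum	ITS1	555	2
Dermoloma	bellerianum	ITS2	486	2
Dermoloma	bellerianum	rpb2	162	2
Dermoloma	bellerianum	ef1a	2751	1
Dermoloma	phaeopodium	ITS1	884	3
Dermoloma	phaeopodium	ITS2	854	3
Dermoloma	phaeopodium	rpb2	798	1
Dermoloma	phaeopodium	ef1a	541	3
Dermoloma	sp. 6	ITS1	495	1
Dermoloma	sp. 6	ITS2	576	1
Dermoloma	sp. 6	rpb2	699	2
Dermoloma	sp. 6	ef1a	122	2
Dermoloma	cf. pusillum	ITS1	627	2
Dermoloma	cf. pusillum	ITS2	418	2
Dermoloma	cf. pusillum	rpb2	0	0
Dermoloma	cf. pusillum	ef1a	479	2
Dermoloma	cuneifolium	ITS1	314	1
Dermoloma	cuneifolium	ITS2	428	1
Dermoloma	cuneifolium	rpb2	99	1
Dermoloma	cuneifolium	ef1a	257	2
Dermoloma	cf. cuneifolium 1	ITS1	298	1
Dermoloma	cf. cuneifolium 1	ITS2	284	1
Dermoloma	cf. cuneifolium 1	rpb2	68	1
Dermoloma	cf. cuneifolium 1	ef1a	114	2
Dermoloma	sp. 3	ITS1	186	2
Dermoloma	sp. 3	ITS2	196	2
Dermoloma	sp. 3	rpb2	88	1
Dermoloma	sp. 3	ef1a	74	1
Dermoloma	pseudocuneifolium	ITS1	93	1
Dermoloma	pseudocuneifolium	ITS2	206	2
Dermoloma	pseudocuneifolium	rpb2	176	1
Dermoloma	pseudocuneifolium	ef1a	39	1
Dermoloma	alexandri	ITS1	80	1
Dermoloma	alexandri	ITS2	142	2
Dermoloma	alexandri	rpb2	36	1
Dermoloma	alexandri	ef1a	67	1
Dermoloma	sp. 11	ITS1	169	2
Dermoloma	sp. 11	ITS2	72	1
Dermoloma	sp. 11	rpb2	35	1
Dermoloma	sp. 11	ef1a	7	1
Dermoloma	cf. pseudocuneifolium	ITS1	82	2
Dermoloma	cf. pseudocuneifolium	ITS2	63	1
Dermoloma	cf. pseudocuneifolium	rpb2	22	1
Dermoloma	cf. pseudocuneifolium	ef1a	7	1
Dermoloma	cf. phaeopodium	ITS1	52	2
Dermoloma	cf. phaeopodium	ITS2	63	2
Dermoloma	cf. phaeopodium	rpb2	12	1
Dermoloma	cf. phaeopodium	ef1a	29	2
Dermoloma	sp. 4	ITS1	16	1
Dermoloma	sp. 4	ITS2	60	1
Dermoloma	sp. 4	rpb2	69	1
Dermoloma	sp. 4	ef1a	3	2
Dermoloma	magicum	ITS1	66	1
Dermoloma	magicum	ITS2	44	1
Dermoloma	magicum	rpb2	14	1
Dermoloma	magicum	ef1a	3	1
Dermoloma	cf. cuneifolium 2	ITS1	34	1
Dermoloma	cf. cuneifolium 2	ITS2	28	1
Dermoloma	cf. cuneifolium 2	rpb2	18	1
Dermoloma	cf. cuneifolium 2	ef1a	3	2
Dermoloma	atrocinereum	ITS1	19	1
Dermoloma	atrocinereum	ITS2	32	2
Dermoloma	atrocinereum	rpb2	10	1
Dermoloma	atrocinereum	ef1a	4	1
Dermoloma	sp. 2	ITS1	24	2
Dermoloma	sp. 2	ITS2	15	2
Dermoloma	sp. 2	rpb2	12	1
Dermoloma	sp. 2	ef1a	2	1
Dermoloma	cf. cuneifolium USA	ITS1	4	1
Dermoloma	cf. cuneifolium USA	ITS2	2	1
Dermoloma	cf. cuneifolium USA	rpb2	0	0
Dermoloma	cf. cuneifolium USA	ef1a	2	1
Hodophilus	foetens	ITS1	4034	2
Hodophilus	foetens	ITS2	4219	1
Hodophilus	foetens	rpb2	1949	1
Hodophilus	foetens	ef1a	1313	1
Hodophilus	atropunctus	ITS1	53	2
Hodophilus	atropunctus	ITS2	55	2
Hodophilus	atropunctus	rpb2	46	1
Hodophilus	atropunctus	ef1a	2609	2
Hodophilus	carpaticus	ITS1	508	1
Hodophilus	carpaticus	ITS2	293	1
Hodophilus	carpaticus	rpb2	554	1
Hodophilus	carpaticus	ef1a	223	1
Hodophilus	micaceus	ITS1	45	1
Hodophilus	micaceus	ITS2	41	1
Hodophilus	micaceus	rpb2	918	1
Hodophilus	micaceus	ef1a	256	1
Hodophilus	phaeoxanthus	ITS1	101	2
Hodophilus	phaeoxanthus	ITS2	79	1
Hodophilus	phaeoxanthus	rpb2	527	1
Hodophilus	phaeoxanthus	ef1a	154	2
Hodophilus	cambriensis	ITS1	18	1
Hodophilus	cambriensis	ITS2	15	1
Hodophilus	cambriensis	rpb2	455	1
Hodophilus	cambriensis	ef1a	142	1
Hodophilus	anatinus	ITS1	99	2
Hodophilus	anatinus	ITS2	173	2
Hodophilus	anatinus	rpb2	205	1
Hodophilus	anatinus	ef1a	95	2
Hodophilus	variabilipes	ITS1	109	1
Hodophilus	variabilipes	ITS2	96	1
Hodophilus	variabilipes	rpb2	101	1
Hodophilus	variabilipes	ef1a	75	2
Hodophilus	stramineus	ITS1	21	1
Hodophilus	stramineus	ITS2	27	2
Hodophilus	stramineus	rpb2	144	2
Hodophilus	stramineus	ef1a	50	1
Hodophilus	pallidus	ITS1	5	1
Hodophilus	pallidus	ITS2	1	1
Hodophilus	pallidus	rpb2	99	1
Hodophilus	pallidus	ef1a	71	2
Hodophilus	phaeophyllus	ITS1	7	1
Hodophilus	phaeophyllus	ITS2	1	1
Hodophilus	phaeophyllus	rpb2	2	2
Hodophilus	phaeophyllus	ef1a	12	1
Russula	sp. 1	ITS1	1767	2
Russula	sp. 1	ITS2	0	0
Russula	sp. 1	rpb2	2480	1
Russula	sp. 1	ef1a	3094	1
Russula	sp. 2	ITS1	1260	1
Russula	sp. 2	ITS2	2525	1
Russula	sp. 2	rpb2	500	1
Russula	sp. 2	ef1a	732	1
Russula	sp. 3	ITS1	684	1
Russula	sp. 3	ITS2	1031	1
Russula	sp. 3	rpb2	1240	2
Russula	sp. 3	ef1a	55	1
Russula	dryadicola	ITS1	583	2
Russula	dryadicola	ITS2	727	2
Russula	dryadicola	rpb2	557	2
Russula	dryadicola	ef1a	302	1
Russula	sp. 4	ITS1	378	1
Russula	sp. 4	ITS2	434	2
Russula	sp. 4	rpb2	90	1
Russula	sp. 4	ef1a	767	1
Russula	mattiroloana	ITS1	214	1
Russula	mattiroloana	ITS2	266	1
Russula	mattiroloana	rpb2	100	1
Russula	mattiroloana	ef1a	0	0
Russula	sp. 5	ITS1	62	1
Russula	sp. 5	ITS2	11	1
Russula	sp. 5	rpb2	16	1
Russula	sp. 5	ef1a	25	1
Russula	globispora	ITS1	52	2
Russula	globispora	ITS2	5	1
Russula	globispora	rpb2	0	0
Russula	globispora	ef1a	0	0
Russula	quercus-floribundae	ITS1	0	0
Russula	quercus-floribundae	ITS2	0	0
Russula	quercus-floribundae	rpb2	16	1
Russula	quercus-floribundae	ef1a	25	1
Russula	abbottabadensis	ITS1	0	0
Russula	abbottabadensis	ITS2	1	1
Russula	abbottabadensis	rpb2	0	0
Russula	abbottabadensis	ef1a	0	0
Russula	ayubiana	ITS1	0	0
Russula	ayubiana	ITS2	0	0
Russula	ayubiana	rpb2	1	1
Russula	ayubiana	ef1a	0	0
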