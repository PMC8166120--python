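subject	y1	y2	y3	mfq_fof	age_c
sub-001	0.4527235815	0.03017268439		3.016986717	11.15904608
sub-002	0.2711255812		-0.5603478624	4.48718618	-9.681539718
sub-003	0.3157915653	0.6237049626	0.3962940612	2.025219185	-2.088648034
sub-004	0.5676340831	0.0863498489		4.47140979	7.660043375
sub-005	0.1303669372			2.544017315	-3.250542503
sub-006	0.3756799418	0.2774761354		2.814233272	0.0007185145537
sub-007	0.2532825648	0.06035925803		3.848989249	-16.14147166
sub-008	0.3644480438	0.02210219411		2.78131192	1.713191964
sub-009	0.3961950193	-0.09856438716	0.08549536825	3.10335012	8.674163996
sub-010	0.2807584457			1.251534432	5.420387274
sub-011	0.564980262		-0.0345968812	3.613223188	7.314467742
sub-012	0.4079418111	0.2736441694	-0.03979287087	3.077097387	1.437455683
sub-013	0.2781746067	0.1053862294	-0.3420547092	2.589471812	-7.054677294
sub-014	0.6479567375	0.1463861355		3.718065597	3.871866769
sub-015	0.1383423235		-0.6553983213	2.521688875	-7.911681767
sub-016	0.4632792942		0.3684942927	2.883834368	5.54952981
sub-017	0.4937057872		0.3993623683	1.983774753	-13.31497011
sub-018	0.06924032376		0.2009271808	2.767047084	5.381931642
sub-019	0.2084347113	0.07447140833		2.236293208	-9.243921561
sub-020	0.3986454841	-0.03385943743	-0.405807848	2.411734033	-4.203296039
sub-021	0.5391998506	0.01491115167	0.2975875047	3.604182963	-5.427056186
sub-022	0.1171990868	0.09295277825		2.461351143	2.096107935
sub-023	0.3813823223	0.1434897707		2.956289162	-8.825743392
sub-024	0.01980484198		0.158167127	4.864314282	-3.776832688
sub-025	0.02037731563	-0.1597678095	-0.3742946165	4.596217926	-18.6740347
sub-026	0.5447676592	0.210374727		3.53284129	-6.649049138
sub-027	0.1810191837		0.3607168966	3.084159111	-3.280725821
sub-028	0.08232619958	0.5379088798	0.2606691159	2.451832898	-11.2762272
sub-029	0.5621271599	0.2909571186	0.5822979088	2.088788278	0.8765339949
sub-030	0.3667013258	-0.1097023243		4.69467662	-4.096043503
sub-031	0.5726056328			3.026670653	2.849254168
sub-032	0.6704368728	0.4419180211	0.148831469	1.90356152	1.302302702
sub-033	0.3306896788	0.2342022319	-0.4330354123	3.276095928	-3.08285714
sub-034	0.1490497669	-0.3912302972		3.681778696	6.6763505
sub-035	0.2641198254	0.4013897642		3.251093881	0.8556593679
sub-036	0.5909728986		0.01517152362	4.249960613	4.955553421
sub-037	-0.02131533207	-0.1568749882	-0.01214462398	1.397537764	-4.892856762
sub-038	0.4041859246	0.007087889308		3.055248701	-0.8975335407
sub-039	-0.01755057561	0.04863349829	-0.02784090007	2.89721782	-8.325349432
sub-040	0.2130075716	0.5750593969	0.3551363038	1.596145044	14.37980299
sub-041	0.1410907475	-0.09478936382	-0.2298308141	3.31913986	-7.11171584
sub-042	0.2238768778			3.942204129	-6.782290198
sub-043	0.1033264185		-0.288922652	3.203787953	-12.75202703
sub-044	-0.04525540774	-0.2112827493		2.405541304	-6.760037221
sub-045	0.4063543473	0.1947072055		3.893342132	3.739629515
sub-046	0.737150909	0.4326202273	0.07852040529	3.011684914	2.238715345
sub-047	0.3929781366	-0.02895894971	0.05146150673	3.014860327	-10.41879537
sub-048	0.3517913288	-0.1136043097		3.611832639	-4.18107566
sub-049	0.331597706		-0.2464081785	2.040129732	-3.286010344
sub-050	0.1696748635			3.820671618	1.534409737
sub-051	-0.04808686171			3.423578509	-2.599372177
sub-052	0.7521741321			3.713893671	-0.05828599188
sub-053	0.4198124304			2.197590703	5.798973837
sub-054	0.1115844635			3.762681404	2.876121163
sub-055	0.7648212006			2.196616971	-4.410690981
sub-056	0.2918264623			1.723401408	-2.746359207
sub-057	0.2866358116			3.952484965	-4.355447088
sub-058	0.6197113491			3.976979351	-11.12478323
sub-059	0.2189897536			4.042085486	-8.136369978
sub-060	0.216547428			2.925978791	-6.156453188
sub-061	0.2367572698			2.444097241	-5.483521925
sub-062	0.2399576975			0.7806215045	-5.507126144
sub-063	0.4573646592			3.329849666	-0.2518456952
sub-064	0.2057251439			3.519610763	11.76629148
sub-065	0.09203850518			3.877396691	4.024621109
sub-066	0.4119204821			2.465309221	4.444736516
sub-067	0.3439900662			2.273441817	3.645815133
sub-068	0.3999567663			3.314286654	0.1491640928
sub-069	0.5060827714			3.77151054	8.611463382
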