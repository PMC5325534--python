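label	total	mapped	paired_in_sequencing	read1	read2	properly_paired	itself_and_mate_mapped	singletons	mate_diff_chr	mate_diff_chr_mapq5
PolishRed_6m	129083165	125618965	129083165	64058541	65024624	104968754	123975096	1643869	5079498	2731309
PolishRed_9m	129828806	127331756	129828806	64383140	65445666	102598750	126102410	1229346	6200605	3836617
PolishRed_12m	86157331	84520505	86157331	42810031	43347300	66969668	83577919	942586	3987897	2423912
PolishHF_6m	78638726	77583615	78638726	38885550	39753176	62926014	77133629	449986	2768888	727097
PolishHF_9m	125158864	123855247	125158864	61933615	63225249	102019446	123246170	609077	3420578	922272
PolishHF_12m	86243971	85516298	86243971	42873038	43370933	72706552	85171918	344380	2146832	568684
Hereford_6m	131040830	129659186	131040830	64929303	66111527	110158835	129106337	552849	3702495	777228
Hereford_9m	126894781	125680372	126894781	62842854	64051927	104811545	125092492	587880	3869208	938567
Hereford_12m	178097598	175913686	178097598	88097058	90000540	148218515	175078651	835035	5065145	1323493
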