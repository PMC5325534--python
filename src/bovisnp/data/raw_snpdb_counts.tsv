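breed	age_months	replicate	only_indels	only_snps	snps_and_indels
Hereford	6	1	6396	330413	336808
Hereford	6	2	6367	344246	350612
Hereford	9	1	3594	290198	293791
Hereford	9	2	4828	297236	302063
Hereford	12	1	6781	361527	368307
Hereford	12	2	8638	429564	438201
PolishRed	6	1	6090	346054	352144
PolishRed	6	2	4804	289124	293928
PolishRed	9	1	12049	325913	337962
PolishRed	9	2	6857	395364	402221
PolishRed	12	1	5778	256349	262127
PolishRed	12	2	6189	341000	347189
PolishHF	6	1	2922	184589	187510
PolishHF	6	2	3496	195466	198961
PolishHF	9	1	6142	297467	303608
PolishHF	9	2	5982	322852	328833
PolishHF	12	1	5133	277258	282390
PolishHF	12	2	5259	249488	254746
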