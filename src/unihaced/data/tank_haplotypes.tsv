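haplotype_id	n_umis	reads	dloop_length	species	identity_pct
1	2	357	1092	Alectis ciliaris	98.7
2	3	3231	1056	Evistias acutirostris	99.9
3	3	4162	1040	Labracoglossa argenteiventris	98.9
4	2	3788	1040	Labracoglossa argenteiventris	98.7
5	2	1471	1040	Labracoglossa argenteiventris	98.8
6	1	1071	1039	Labracoglossa argenteiventris	98.9
7	1	826	1037	Labracoglossa argenteiventris	99.5
8	1	131	1044	Labracoglossa argenteiventris	97.6
9	1	7	1039	Labracoglossa argenteiventris	98.4
10	2	4931	1096	Parupeneus ciliatus	97.5
11	1	6311	1076	Trachurus japonicus	99.4
12	1	2220	1076	Trachurus japonicus	99.6
13	1	965	1076	Trachurus japonicus	99.1
14	1	592	1076	Trachurus japonicus	99.8
15	1	340	1076	Trachurus japonicus	99.4
16	3	334	1076	Trachurus japonicus	99.4
17	1	205	1076	Trachurus japonicus	99.3
18	1	26	1070	Trachurus japonicus	98.1
19	1	10	1070	Trachurus japonicus	96.3
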