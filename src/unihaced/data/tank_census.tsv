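species	group	n_individuals
Alectis ciliaris	kept	2
Centropyge ferrugata	kept	4
Centropyge tibicen	kept	1
Chaetodon auripes	kept	1
Chaetodon nippon	kept	3
Chromis notata	kept	4
Evistias acutirostris	kept	4
Labracoglossa argenteiventris	kept	25
Labroides dimidiatus	kept	1
Parupeneus ciliatus	kept	4
Pomacanthus semicirculatus	kept	1
Prionurus scalprum	kept	1
Pterois lunulata	kept	2
Thalassoma cupido	kept	6
Trachurus japonicus	food
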