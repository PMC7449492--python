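Syndrome	Chromosome	Start position	End position
1p36 deletion	1	564424	21598492
Wolf-Hirschhorn	4	85040	2010761
Cri-du-chat	5	1	15678560
Angelman/Prader-Willi	15	22779922	28559437
DiGeorge	22	18661724	21505417
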