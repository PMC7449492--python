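Syndrome	0-1Mb	1-2Mb	2-3Mb	3-4Mb	4-5Mb	5-10Mb	10-40Mb
1p36 deletion	8	20	15	13	12	27	5
Wolf-Hirschhorn	0	5	5	12	5	11	10
Cri-du-chat	0	2	2	3	4	8	31
Angelman/Prader-Willi	6	0	0	1	48	34	1
DiGeorge	12	22	205	6	0	0	0
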