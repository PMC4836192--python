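# SYNTHETIC allele frequencies -- European-plausible stand-in values, not
# measured data.  Tables are deliberately incomplete per locus (rare alleles
# omitted, sums < 1); every allele appearing in tables_2_3.tsv is covered.
locus	allele	frequency
D13S317	8	0.12
D13S317	9	0.07
D13S317	10	0.06
D13S317	11	0.32
D13S317	12	0.25
D13S317	13	0.11
D21S11	28	0.16
D21S11	29	0.22
D21S11	30.2	0.03
D21S11	31.2	0.10
D21S11	32.2	0.13
D18S51	14	0.17
D18S51	15	0.14
D18S51	16	0.12
D18S51	17	0.13
D18S51	18	0.08
TH01	6	0.23
TH01	7	0.17
TH01	8	0.11
TH01	9	0.17
TH01	9.3	0.30
D5S818	8	0.06
D5S818	11	0.36
D5S818	12	0.37
D5S818	13	0.15
FGA	20	0.14
FGA	21	0.17
FGA	22	0.19
FGA	23	0.16
FGA	24	0.14
D3S1358	15	0.26
D3S1358	16	0.24
D3S1358	17	0.21
D3S1358	18	0.15
VWA	16	0.21
VWA	17	0.27
VWA	18	0.22
VWA	19	0.09
D8S1179	12	0.18
D8S1179	13	0.30
D8S1179	14	0.17
D8S1179	15	0.11
D7S820	8	0.16
D7S820	9	0.15
D7S820	10	0.25
D7S820	11	0.21
D16S639	11	0.29
D16S639	12	0.29
D16S639	13	0.17
D2S1338	17	0.19
D2S1338	18	0.09
D2S1338	19	0.12
D2S1338	24	0.12
D2S1338	25	0.11
D19S433	13	0.26
D19S433	14	0.35
D19S433	15	0.16
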