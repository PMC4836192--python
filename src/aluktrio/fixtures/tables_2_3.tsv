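# Consensus STR fingerprints for the prehistoric trio and modern controls.
# Heptaplex panel (amelogenin + 6 systems) for all five individuals, plus
# seven additional systems typed for the trio only.
# source_bone notes which skeletal element yielded the consensus genotype;
# the daughter's D16S639/D2S1338/D19S433 results come from her left humerus
# (DO 3994), all other trio results from the left femora.
sample_id	locus	allele1	allele2	source_bone
DO1911	Amelogenin	X	Y	DO1911
DO1911	D13S317	12	12	DO1911
DO1911	D21S11	30.2	32.2	DO1911
DO1911	D18S51	15	17	DO1911
DO1911	TH01	9.3	9.3	DO1911
DO1911	D5S818	11	12	DO1911
DO1911	FGA	21	22	DO1911
DO1911	D3S1358	16	18	DO1911
DO1911	VWA	17	19	DO1911
DO1911	D8S1179	13	13	DO1911
DO1911	D7S820	8	11	DO1911
DO1911	D16S639	12	13	DO1911
DO1911	D2S1338	18	19	DO1911
DO1911	D19S433	14	15	DO1911
DO3756	Amelogenin	X	X	DO3756
DO3756	D13S317	8	9	DO3756
DO3756	D21S11	28	29	DO3756
DO3756	D18S51	16	16	DO3756
DO3756	TH01	9	9.3	DO3756
DO3756	D5S818	12	12	DO3756
DO3756	FGA	21	23	DO3756
DO3756	D3S1358	18	18	DO3756
DO3756	VWA	17	19	DO3756
DO3756	D8S1179	12	15	DO3756
DO3756	D7S820	10	10	DO3756
DO3756	D16S639	12	13	DO3756
DO3756	D2S1338	24	25	DO3756
DO3756	D19S433	13	14	DO3756
DO3750	Amelogenin	X	X	DO3750
DO3750	D13S317	9	12	DO3750
DO3750	D21S11	29	32.2	DO3750
DO3750	D18S51	16	17	DO3750
DO3750	TH01	9	9.3	DO3750
DO3750	D5S818	11	12	DO3750
DO3750	FGA	21	23	DO3750
DO3750	D3S1358	16	18	DO3750
DO3750	VWA	17	17	DO3750
DO3750	D8S1179	12	13	DO3750
DO3750	D7S820	8	10	DO3750
DO3750	D16S639	12	13	DO3994
DO3750	D2S1338	19	25	DO3994
DO3750	D19S433	14	14	DO3994
Cau_1	Amelogenin	X	Y	Cau_1
Cau_1	D13S317	12	13	Cau_1
Cau_1	D21S11	28	32.2	Cau_1
Cau_1	D18S51	15	18	Cau_1
Cau_1	TH01	9	9.3	Cau_1
Cau_1	D5S818	11	13	Cau_1
Cau_1	FGA	20	21	Cau_1
Cau_2	Amelogenin	X	Y	Cau_2
Cau_2	D13S317	10	11	Cau_2
Cau_2	D21S11	28	31.2	Cau_2
Cau_2	D18S51	14	14	Cau_2
Cau_2	TH01	9.3	9.3	Cau_2
Cau_2	D5S818	8	12	Cau_2
Cau_2	FGA	22	24	Cau_2
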