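# Per-sample FAP/IAP band observations at 30 Alu insertion loci for the
# prehistoric trio, reconstructed from the study's running-text accounting:
# 22 loci definite from flanking-primer amplification alone; internal-primer
# bands for the daughter rescue Alu_3/14/19/20 (total FAP failure) and turn
# Alu_16/26/27 into combined-result heterozygotes; Alu_2 and Alu_7 stay
# incongruent with the family situation; Alu_4 and Alu_25 could not be
# retested (depleted extract).  Band patterns at loci whose genotypes the
# text does not print are SYNTHETIC congruent placeholders.
sample_id	locus	fap_presence	fap_absence	iap	ancient
DO1911	Alu_1	seen	seen	not_tested	true
DO3756	Alu_1	seen	seen	not_tested	true
DO3750	Alu_1	seen	seen	not_tested	true
DO1911	Alu_2	not_seen	seen	not_tested	true
DO3756	Alu_2	not_seen	seen	not_tested	true
DO3750	Alu_2	seen	not_seen	not_tested	true
DO1911	Alu_3	seen	not_seen	not_tested	true
DO3756	Alu_3	seen	not_seen	not_tested	true
DO3750	Alu_3	not_seen	not_seen	band	true
DO1911	Alu_4	seen	not_seen	not_tested	true
DO3756	Alu_4	seen	seen	not_tested	true
DO3750	Alu_4	not_seen	not_seen	extract_depleted	true
DO1911	Alu_5	seen	not_seen	not_tested	true
DO3756	Alu_5	seen	not_seen	not_tested	true
DO3750	Alu_5	seen	not_seen	not_tested	true
DO1911	Alu_6	not_seen	seen	not_tested	true
DO3756	Alu_6	not_seen	seen	not_tested	true
DO3750	Alu_6	not_seen	seen	not_tested	true
DO1911	Alu_7	not_seen	seen	not_tested	true
DO3756	Alu_7	not_seen	seen	not_tested	true
DO3750	Alu_7	seen	seen	not_tested	true
DO1911	Alu_8	seen	not_seen	not_tested	true
DO3756	Alu_8	not_seen	seen	not_tested	true
DO3750	Alu_8	seen	seen	not_tested	true
DO1911	Alu_9	seen	seen	not_tested	true
DO3756	Alu_9	not_seen	seen	not_tested	true
DO3750	Alu_9	not_seen	seen	not_tested	true
DO1911	Alu_10	seen	not_seen	not_tested	true
DO3756	Alu_10	seen	seen	not_tested	true
DO3750	Alu_10	seen	not_seen	not_tested	true
DO1911	Alu_11	not_seen	seen	not_tested	true
DO3756	Alu_11	seen	seen	not_tested	true
DO3750	Alu_11	seen	seen	not_tested	true
DO1911	Alu_12	seen	seen	not_tested	true
DO3756	Alu_12	seen	seen	not_tested	true
DO3750	Alu_12	not_seen	seen	not_tested	true
DO1911	Alu_13	seen	not_seen	not_tested	true
DO3756	Alu_13	seen	not_seen	not_tested	true
DO3750	Alu_13	seen	seen	not_tested	true
DO1911	Alu_14	seen	seen	not_tested	true
DO3756	Alu_14	seen	not_seen	not_tested	true
DO3750	Alu_14	not_seen	not_seen	band	true
DO1911	Alu_15	seen	seen	not_tested	true
DO3756	Alu_15	not_seen	seen	not_tested	true
DO3750	Alu_15	seen	seen	not_tested	true
DO1911	Alu_16	seen	not_seen	not_tested	true
DO3756	Alu_16	not_seen	seen	not_tested	true
DO3750	Alu_16	not_seen	seen	band	true
DO1911	Alu_17	not_seen	seen	not_tested	true
DO3756	Alu_17	seen	seen	not_tested	true
DO3750	Alu_17	not_seen	seen	not_tested	true
DO1911	Alu_18	seen	not_seen	not_tested	true
DO3756	Alu_18	seen	seen	not_tested	true
DO3750	Alu_18	seen	seen	not_tested	true
DO1911	Alu_19	seen	not_seen	not_tested	true
DO3756	Alu_19	not_seen	seen	not_tested	true
DO3750	Alu_19	not_seen	not_seen	band	true
DO1911	Alu_20	seen	seen	not_tested	true
DO3756	Alu_20	seen	seen	not_tested	true
DO3750	Alu_20	not_seen	not_seen	band	true
DO1911	Alu_21	seen	seen	not_tested	true
DO3756	Alu_21	seen	not_seen	not_tested	true
DO3750	Alu_21	seen	not_seen	not_tested	true
DO1911	Alu_22	not_seen	seen	not_tested	true
DO3756	Alu_22	not_seen	seen	not_tested	true
DO3750	Alu_22	not_seen	seen	not_tested	true
DO1911	Alu_23	seen	not_seen	not_tested	true
DO3756	Alu_23	not_seen	seen	not_tested	true
DO3750	Alu_23	not_seen	seen	not_tested	true
DO1911	Alu_24	seen	seen	not_tested	true
DO3756	Alu_24	seen	seen	not_tested	true
DO3750	Alu_24	seen	not_seen	not_tested	true
DO1911	Alu_25	seen	seen	not_tested	true
DO3756	Alu_25	not_seen	seen	not_tested	true
DO3750	Alu_25	not_seen	not_seen	extract_depleted	true
DO1911	Alu_26	seen	seen	not_tested	true
DO3756	Alu_26	not_seen	seen	not_tested	true
DO3750	Alu_26	not_seen	seen	band	true
DO1911	Alu_27	seen	not_seen	not_tested	true
DO3756	Alu_27	seen	seen	not_tested	true
DO3750	Alu_27	not_seen	seen	band	true
DO1911	Alu_28	seen	not_seen	not_tested	true
DO3756	Alu_28	seen	not_seen	not_tested	true
DO3750	Alu_28	not_seen	seen	not_tested	true
DO1911	Alu_29	seen	seen	not_tested	true
DO3756	Alu_29	seen	not_seen	not_tested	true
DO3750	Alu_29	seen	seen	not_tested	true
DO1911	Alu_30	not_seen	seen	not_tested	true
DO3756	Alu_30	seen	seen	not_tested	true
DO3750	Alu_30	seen	not_seen	not_tested	true
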