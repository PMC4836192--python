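# SYNTHETIC amplicon geometry for the 30 Alu insertion loci: flanking-primer
# presence amplicons of 450-500 bp, absence amplicons one Alu-insert (~300 bp)
# shorter, internal-primer amplicons of 118-194 bp.  Reverse orientation means
# the internal primer pairs with the reverse flanking primer.
locus_id	subfamily	presence_len	absence_len	iap_len	orientation
Alu_1	AluYa5	478	170	142	forward
Alu_2	AluYb8	463	158	171	forward
Alu_3	AluYa5	494	186	118	forward
Alu_4	AluYa5	455	149	135	forward
Alu_5	AluYb8	487	179	163	reverse
Alu_6	AluYa5	469	161	150	forward
Alu_7	AluYb8	499	191	186	forward
Alu_8	other	471	165	147	forward
Alu_9	AluYa5	458	152	129	forward
Alu_10	AluYb8	482	174	156	reverse
Alu_11	AluYa5	490	182	139	forward
Alu_12	AluYb8	466	160	168	forward
Alu_13	AluYa5	452	146	124	forward
Alu_14	AluYb8	495	187	194	reverse
Alu_15	other	474	168	133	forward
Alu_16	AluYa5	486	178	152	forward
Alu_17	AluYb8	461	155	145	forward
Alu_18	AluYa5	479	171	160	forward
Alu_19	AluYb8	492	184	176	reverse
Alu_20	AluYa5	457	151	122	forward
Alu_21	AluYb8	483	175	148	forward
Alu_22	AluYa5	468	162	137	forward
Alu_23	other	497	189	182	forward
Alu_24	AluYa5	453	147	126	forward
Alu_25	AluYb8	488	180	158	forward
Alu_26	AluYa5	476	169	144	reverse
Alu_27	AluYb8	464	157	131	forward
Alu_28	AluYa5	491	183	166	forward
Alu_29	other	459	153	120	forward
Alu_30	AluYa5	481	173	154	forward
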