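histone_family	ce_site	ref_site	ptm_type	sample	occurrences
H2A	K5	K5	ac	embryo	3
H2A	K8	K9	ac	embryo	3
H2A	K10	R11	ac	embryo	3
H2A	K96	K95	ac	sperm	1
H2A	K96	K95	ac	embryo	2
H2A	K119	K118	ac	embryo	6
H2B	K7	K12	ac	embryo	9
H2B	K10	K15	ac	sperm	1
H2B	K10	K15	ac	embryo	20
H2B	K11	K16	ac	sperm	1
H2B	K11	K16	ac	embryo	25
H2B	K14	K20	ac	sperm	3
H2B	K14	K20	ac	embryo	63
H2B	K21	K24	ac	embryo	6
H2B	K105	K108	ac	embryo	3
H2B	K113	K116	ac	embryo	1
H3	K9	K9	ac	sperm	1
H3	K14	K14	ac	sperm	2
H3	K14	K14	ac	embryo	3
H3	K23	K23	ac	sperm	2
H3	K23	K23	me1	sperm	1
H3	K23	K23	me2	sperm	6
H3	K23	K23	me3	sperm	5
H3	K23	K23	ac	embryo	3
H3	K23	K23	me1	embryo	2
H3	K23	K23	me2	embryo	44
H3	K23	K23	me3	embryo	4
H3	K27	K27	ac	sperm	3
H3	K27	K27	ac	embryo	6
H3	K27	K27	me2	embryo	16
H3	K27	K27	me3	embryo	47
H3	K36	K36	ac	sperm	34
H3	K36	K36	me1	sperm	5
H3	K36	K36	me2	sperm	6
H3	K36	K36	me3	sperm	5
H3	K36	K36	ac	embryo	11
H3	K36	K36	me2	embryo	2
H3	K79	K79	me1	sperm	9
H3	K79	K79	me2	sperm	25
H3	K79	K79	me1	embryo	10
H3	K79	K79	me2	embryo	5
H4	K5	K5	ac	sperm	1
H4	K5	K5	ac	embryo	1
H4	K8	K8	ac	embryo	9
H4	K12	K12	ac	sperm	1
H4	K12	K12	ac	embryo	9
H4	K16	K16	ac	embryo	4
H4	K20	K20	me1	sperm	9
H4	K20	K20	me2	sperm	13
H4	K20	K20	me2	embryo	1
H4	K31	K31	ac	embryo	3
H4	K59	K59	ac	embryo	1
H4	K79	K79	ac	sperm	1
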