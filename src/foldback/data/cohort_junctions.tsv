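subject	chrom_arm	cnv_type	deletion_bp	duplication_bp	spacer_bp	capture_method	inheritance	dis_inv	inv_tel	inv_tra
SGTel022	2q	inv_dup_term_del	6191297	4559194	1459	PCR	unknown	1	0	0
EGL044	2q	inv_dup_term_del	5803294	41659284	2047	SureSelect+PCR	de_novo	1	1	0
SGTel014	2q	inv_dup_term_del	3284385	8846045	9316	PCR	de_novo	1	0	0
EGL395	2q	inv_dup_term_del	3262416	5006517	2914	PCR	de_novo	1	0	0
EGL014	4p	inv_dup_term_del	561480	2462234	3428	PCR	unknown	1	0	0
SGTel013	4p	inv_dup_term_del	4470923	1045252	3948	PCR	de_novo	1	0	0
SGTel015	5p	inv_dup_term_del	18804928	27181320	3993	PCR	unknown	1	0	0
EGL106	5p	inv_dup_term_del	25750936	1405992	3138	PCR	unknown	1	1	0
EGL399	7q	inv_dup_translocation	2335653	12392	5040	PCR	de_novo	0	0	1
EGL074	9p	inv_dup_translocation	10358949	811440	7486	SureSelect+PCR	unknown	1	0	0
M397	9p	inv_dup_translocation	10481181	1461954	3450	SureSelect+PCR	unknown	1	0	1
EGL104	9p	inv_dup_term_del	10503832	2786015	14779	PCR	unknown	1	1	0
SGTel019	13q	inv_dup_term_del	1496671	6628755	9009	PCR	unknown	1	0	0
18q-207c	18q	inv_dup_term_del	28547996	947547	9519	PCR	de_novo	1	1	0
EGL099	18q	inv_dup_term_del	22238039	5508846	5489	PCR	unknown	1	0	0
18q-26c	18q	inv_dup_term_del	20952219	211862	766	SureSelect+InversePCR	de_novo	1	1	0
18q-6c	18q	inv_dup_term_del	20032810	595310	1866	PCR	de_novo	1	1	0
18q-34c	18q	inv_dup_term_del	20009964	8936902	4035	PCR	de_novo	0	1	0
18q-223c	18q	inv_dup_term_del	16438679	922294	1543	PCR	de_novo	1	1	0
SGTel009	18q	inv_dup_term_del	14869902	4787035	700	PCR	unknown	0	1	0
18q-65c	18q	inv_dup_term_del	14644742	14462430	2136	PCR	de_novo	1	1	0
18q-139c	18q	inv_dup_term_del	12951972	1899319	951	PCR	de_novo	1	0	0
18q-233c	18q	inv_dup_term_del	9592937	181800	70466	PCR	de_novo	1	0	0
18q-107c	18q	inv_dup_term_del	8539434	5703158	1822	PCR	de_novo	1	0	0
M396	18q	inv_dup_translocation	3438438	10434	724	PCR	maternal	0	0	1
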