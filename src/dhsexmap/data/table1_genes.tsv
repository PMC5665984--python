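# The 13 gene models of the Y-chromosome non-recombining sex-determination region.
# anchored=False marks gene models placed within the sex-linked recombination bin but on
# small contigs that could not be anchored onto the optical map.
# hemizygous_table: the published table title counts all 13 genes as hemizygous.
# hemizygous_per_text: the accompanying prose reports twelve of thirteen gene predictions
# missing from XX females without identifying the exception, so the per-gene status from
# the text is unresolved for every row.
gene_id	annotation	anchored	hemizygous_table	hemizygous_per_text
AsparagusV1_01.231	Suppressor of Female Function (SOFF)	True	True	unresolved
AsparagusV1_01.232	Unannotated	True	True	unresolved
AsparagusV1_01.233	Transformation/transcription domain-associated protein	True	True	unresolved
AsparagusV1_01.234	Unannotated	True	True	unresolved
AsparagusV1_01.235	AP2 ethylene-responsive transcription factor	True	True	unresolved
AsparagusV1_01.236	Nudix hydrolase 15, mitochondrial-like	True	True	unresolved
AsparagusV1_01.240	DEFECTIVE IN TAPETUM DEVELOPMENT AND FUNCTION 1 (TDF1)	True	True	unresolved
AsparagusV1_01.247	Unannotated	False	True	unresolved
AsparagusV1_01.248	Outer envelope protein 80, chloroplastic-like isoform X1	False	True	unresolved
AsparagusV1_01.272	Photosystem I reaction center subunit XI, chloroplastic	False	True	unresolved
AsparagusV1_01.273	Photosystem I reaction center subunit XI, chloroplastic	False	True	unresolved
AsparagusV1_01.274	Unannotated	False	True	unresolved
AsparagusV1_01.275	Unannotated	False	True	unresolved
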