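gene	mutation_id	aa_change	cds_change	description	primary_site	primary_histology	sample	pubmed
EGFR	COSM00001	p.L858M	c.2572C>A	Substitution - Missense	lung	carcinoma	TCGA-0001	PubMed:15118073
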