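GENE	EGFR
DOMAIN	Protein kinase	712	979	PF07714
FEATURE	ModifiedResidue	869	869	Phosphotyrosine
LOCATION	Cell membrane
TISSUE	Ubiquitous
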