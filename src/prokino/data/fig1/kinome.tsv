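symbol	synonyms	group	family	subfamily	chromosome
EGFR	EGFRvIII;ERBB1;ERBB;mENA	TK	EGFR	-	7p12
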