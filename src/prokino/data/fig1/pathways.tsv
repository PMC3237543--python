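PATHWAY	P1	Signaling by EGFR	EGFR
COMPLEX	C1	EGF:EGFR [plasma membrane]
COMPLEX	C2	EGF:EGFR dimer [plasma membrane]
REACTION	R1	EGFR dimerization	P1	consumes=C1	produces=C2
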