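>EGFR worked-example kinase sequence
ISQQVSTMCNEVDRFSHDNSFPPFAVAMSTDTIHVTEMAFCKQGWPQFRQQHCRPMKHAM
TVKGLNDELNEPYDCEMCRWMCEVVTPKQGIAEQRDQDCRSFIGNHIYGHNYHKEWRDCH
RCDPRVNDEFEQQGKTSAVAWARPGRYWQTTPVQIRWMDGLFHHQRTIECFMPVDHMILA
LCVWLHQMWTEVWYVLSEQSFDQHSRAPVNGQCNSMQPPSHENNISKVMCFLWIPVSQVW
FIQNMDDDPEWHVNNHPTYKKQDDHWYGKCTFVQKAKCQVAMRWFMRLPFMSEDQDFHCQ
IYHHDCCDAKQILKTNIMNYKTHHYRDTHPIVMIDCPSFCTDGMNWITLAFYCQYIVINN
MSKKHVLLFDIPSAILEHGMFDLVRMERDTKEFGVTGMLTTKDFHFIWLTCHNSFRCEGI
ALHQMPRVMYLHHRNVICRVYMWHGHEQFTDYCRPLWKYGQLPDYMFTCIQCKIVWNNPW
LKQFTFIQTTRLYSGPNMWFGVALWHQELMPNWVIKEPPYRLVVLGWRDSLMAVWKLVTA
VPGPSHGIKQPLYHGFAEEPFQPYVRMKTQHSPMCATQQDMEHKSNASPDHSAIYYMKIP
SFAKQNYYGGVEWSNIAIACYFTWIEYSAWVGNALWYRTKVPPLTRIMSKNELCIDGANF
AYRCMHRSVKQGYFHTHSCEYGLWTMCSVAWDGSRWDQFCSTQKIASQFAQVAMMIEMGS
GSFGHTLTPILKRAWMMWKTHIFDVAIKLFSVRHHAMETSSHELMYKFPEKHDCYCLLEF
REFTKEVAWTQRTMGEYLPTRYGNGDGNKTEKLADNTTWHCESLPYLNSEMIPKHRDLRA
GSNWKRKFKFGEYFDFGLCNFCKGEMTYCDAQIWCFAPENRREERCLIIDQFNNHDLWSC
ANYCYYQHRPAVRAPIKWSEQWTWFRMMGESNMIKLLEWMTDDPKNDIIVNIKYYDNAFR
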