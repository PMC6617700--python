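>VAMP2_synthetic synthetic codon-level stand-in for the human VAMP2 CDS (85 G/C-ending + 31 A/T-ending sense codons of 117)
ATGAGCGCCACCGCCGCCACCGCCCCCCCCGCCGCCCCCGCCGGCGAGGGCGGCCCCCCCGCCCCCCCCC
CCAACCTCACCAGCAACAGGAGGCTCCAGCAGACCCAGGCCCAGGTCGACGAGGTCGTCGACATCATGAG
GGTCAACGTCGACAAGGTCCTCGAGAGGGACCAGAAGCTCAGCGAGCTCGACGACAGGGCCGACGCCCTC
CAGGCCGGCGCCAGCCAGTTCGAGACCAGCGCAGCAAAACTAAAAAGAAAATATTGGTGGAAAAATCTAA
AAATGATGATAATAATGGGAGTAATATGTGCAATAATACTAATAATAATAATAGTATATTTTAGTACATA
A
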