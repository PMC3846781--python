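>CHIPlike_synthetic constructed 303-codon CDS; codons 130/147/165/207/236 = AAC/TGG/CTC/TAC/AGC; not the NM_005861 sequence
ATGACGGAGTACGAGTCAGTGCAACTTGTTGCCCAAACTACTGCCTCCATATGGTATCAT
TGTGGGAGACGTGACGTGCCAAAACGCACGCGTTTCCCGGTCAGATCGGGTTTAACTAAA
TCAAGTAACCGTAAAGATCGATCGCTCGCTTTTGTTTCTCAAGACGCGTGGGACCGTAGG
CTTTCAATCTTTAAGCTTAGGGCAAAACTCCTATCATGCTTTTTTGATGCCCCCGGACAG
GTTTTCAATCACGTATATCCCTCTACAAGCCTTGTGTTGCCCGTGGGAAAGAGTGATCCT
GGTTCGGCAAGCCCTCAACGTAAAAAGACCTCGCAGGCGGGGGATAATGGTGAACCTTTA
TTGGTAGTTAACCCTTCCGATGAAGAAAACATCGAGGCAGTTGTCATCTGGTCGGTGCGG
GATGGAATTCGCGTATTTTGGCGAGAGTGGATGTGGAATCCCTCGATAGTCGAACATCTA
GATTCGGGCGGACTCACGCCGCAGGTTCGGATCGTACTTGCTTCTATAGGTTTCAACTGC
GAATCGAATGAGATACCGGCCCCAGGCTCTAGCACTGAAAGCGGAATGCCGGGCCTACTC
TTCCAGTTAGCTAGCTGTTACTCATCCGTATTACTGGAACCAGCGCTCATCTGCTTAAGT
AGCGGTTGTGGCACCGTCTCCTACGAGTCGCTAGAACGCGCATCGAGCCGTAAACTTATA
TATGATGTCGGGCCCGCAGCGGGAGCACATCTGCAGATATACAATGGTTCTAGGACTCTG
TACCTAAAGGCGGAGTCTCAAGCAGAAATCTGTAGCGACGAATGCGTACGACCGAAATCA
ACAGACGAGACTACACAGTCAAGAACCTCCAATATTAACTGTTGGTCGCTCACATGGGAG
TCTTATCACTAA
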