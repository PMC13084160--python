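name,set,sequence,role
tRNA-Gly-CCC-2-1_ASO,ASO,TCACCCGCGTGGGAGGCGAGAA,ASO
tRNA-Gly-GCC-1-1_ASO,ASO,CCTCCCGCGTGGCAGGCGAGAA,ASO
tRNA-Gly-UCC-1-1_ASO,ASO,CAACTGCTTGGAAGGCAGCTAT,ASO
Scrambled ASO,ASO,ACGGTCGCCCAGCTGGAAAGGG,ASO
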