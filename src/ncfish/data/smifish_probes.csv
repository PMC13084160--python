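name,set,sequence,role
Gars1_1,Gars1,GTAGAAAAACCTCCTCTTCAAC,smiFISH probe
Gars1_2,Gars1,CTCCATAAATAGCAAAAGCCTG,smiFISH probe
Gars1_3,Gars1,CGAAGTCATACAATCCACTGAC,smiFISH probe
Gars1_4,Gars1,GATCTGCTCCTCTTGGATAAAG,smiFISH probe
Gars1_5,Gars1,AGAGGTCTTTAAAACTGGCTCA,smiFISH probe
Gars1_6,Gars1,ATAGTTATCAAGCTGGGCCAAG,smiFISH probe
Gars1_7,Gars1,TAAAAGGTACCGGAGGGGACAG,smiFISH probe
Gars1_8,Gars1,CCAATGAAGGTCTGGAACATTA,smiFISH probe
Gars1_9,Gars1,CTCAGATATCCAGGCATATTTC,smiFISH probe
Gars1_10,Gars1,TTTCTCAGTGGGATCTACAAAG,smiFISH probe
Gars1_11,Gars1,CACACTTTGGAACTTGGGATGG,smiFISH probe
Gars1_12,Gars1,TTAATCACACCCTGTTCAACAG,smiFISH probe
Gars1_13,Gars1,CTTCGTGAGGTAGAGGTAGATG,smiFISH probe
Gars1_14,Gars1,CGGAGTTTATCAGGAGATATTC,smiFISH probe
Gars1_15,Gars1,CTCAGCTACTAGTGGAACTTTG,smiFISH probe
Gars1_16,Gars1,TTGTTGGGCTCAAACTGTACAA,smiFISH probe
Gars1_17,Gars1,AAATGTAGCACTCATCACAGGC,smiFISH probe
Gars1_18,Gars1,TCTCGGACATGGAATGTATGTT,smiFISH probe
Gars1_19,Gars1,AACTGAAGAACGTTCTCTGTTC,smiFISH probe
Gars1_20,Gars1,TCAGTGGAAGGACAGAACATTT,smiFISH probe
Gars1_21,Gars1,AATAGTGATGCCGAAAGCCACG,smiFISH probe
Gars1_22,Gars1,CGTCTTGTTCACTGTATCAAAG,smiFISH probe
Gars1_23,Gars1,TATTAGCACGATGGTCATAAGC,smiFISH probe
Gars1_24,Gars1,GTGTAGTGGACATGATGAGTTA,smiFISH probe
tRNA-Gly-CCC-2-1_probe 1,tRNA-Gly-CCC-2-1,TCTACCATTGAACTACCAATGC,smiFISH probe
tRNA-Gly-CCC-2-1_probe 2,tRNA-Gly-CCC-2-1,TCACCCGCGTGGGAGGCGAGAA,smiFISH probe
tRNA-Gly-CCC-2-1_probe 3,tRNA-Gly-CCC-2-1,CATTGGCCGGGAATCGAACCCG,smiFISH probe
tRNA-Gly-GCC-1-1_probe 1,tRNA-Gly-GCC-1-1,TCTACCACTGAACCACCCATGC,smiFISH probe
tRNA-Gly-GCC-1-1_probe 2,tRNA-Gly-GCC-1-1,CCTCCCGCGTGGCAGGCGAGAA,smiFISH probe
tRNA-Gly-GCC-1-1_probe 3,tRNA-Gly-GCC-1-1,CATGGGCCGGGAATCGAACCCG,smiFISH probe
tRNA-Gly-UCC-1-1_probe 1,tRNA-Gly-UCC-1-1,CTCACCACTATACCACCAACGC,smiFISH probe
tRNA-Gly-UCC-1-1_probe 2,tRNA-Gly-UCC-1-1,CAACTGCTTGGAAGGCAGCTAT,smiFISH probe
tRNA-Gly-UCC-1-1_probe 3,tRNA-Gly-UCC-1-1,CGTTGGCCGGGAATCGAACCCG,smiFISH probe
Scrambled_1,Scrambled,CCGCACATGACTCTTAAATTAC,smiFISH probe
Scrambled_2,Scrambled,ACGGTCGCCCAGCTGGAAAGGG,smiFISH probe
Scrambled_3,Scrambled,GCTTAGCTCCCGGGCAAGGAAC,smiFISH probe
tRNA_Lys_CUU_12_1_1,tRNA_Lys_CUU_12_1,TCTACAGACTGAGCTAGCTGGG,smiFISH probe
tRNA_Lys_CUU_12_1_2,tRNA_Lys_CUU_12_1,ACCCTGAGACTAAGAGTCTCAT,smiFISH probe
tRNA_Lys_CUU_12_1_3,tRNA_Lys_CUU_12_1,CACAACATGGGGCTCCAACCCA,smiFISH probe
tRNA-Lys-UUU-1-1_1,tRNA-Lys-UUU-1-1,CTACCGACTGAGCTATCCGGGC,smiFISH probe
tRNA-Lys-UUU-1-1_2,tRNA-Lys-UUU-1-1,CCCTCAGATTAAAAGTCTGATG,smiFISH probe
tRNA-Lys-UUU-1-1_3,tRNA-Lys-UUU-1-1,CCGAACAGGGACTTGAACCCTG,smiFISH probe
Cox7c-1,Cox7c,ATCATAGCCAGCAACCGCCACTTGTT,smiFISH probe
Cox7c-2,Cox7c,TCATAGTGGCTGCGACGGACCACGGA,smiFISH probe
Cox7c-3,Cox7c,CTTGCTCGGCAGAGCGCGAAGACCGA,smiFISH probe
Cox7c-4,Cox7c,TCAGATCATCTCTTAAACTTTCTTCATTCTGT,smiFISH probe
Cox7c-5,Cox7c,CGGACCACGGAGGTCGTGAACCTCCG,smiFISH probe
Cox7c-6,Cox7c,CTGGAAGTTCTGCGAGGGCCGCAGAC,smiFISH probe
Cox7c-7,Cox7c,CCTTTCTACACGACCTTGCTCGGCAG,smiFISH probe
Cox7c-8,Cox7c,TAGCTGGTGTCTTACTATAAAGAAAGGTGCGG,smiFISH probe
Cox7c-9,Cox7c,AGAAAGGTGCGGCAAACCCAGATCCAAAG,smiFISH probe
Cox7c-10,Cox7c,CCAGATCCAAAGTACACGGTCATCATAGC,smiFISH probe
Cox7c-11,Cox7c,GGCCCAACATGTCGCTGCTGGAAGTT,smiFISH probe
Cox7c-12,Cox7c,AGGGCCGCAGACACGGAAGGCGGAAG,smiFISH probe
Cox7c-13,Cox7c,GGAAGGCGGAAGAAATGGCCGTACCACC,smiFISH probe
Cox7c-14,Cox7c,CGTACCACCTAACTCCCCTTTCTACA,smiFISH probe
Cox7c-15,Cox7c,CCGCCACTTGTTTTCCACTGAAAATGGC,smiFISH probe
Cox7c-16,Cox7c,CTGAAAATGGCAAATTCTTCCCCGGACC,smiFISH probe
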