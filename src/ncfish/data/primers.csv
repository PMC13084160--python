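name,lab_number,sequence
Gars1_qPCR_F,380,AGACCATCCCAAGTTCCAAAG
Gars1_qPCR_R,381,TTCAACAGCATCTCCCAGAC
ActB_qPCR_F,238,ACCTTCTACAATGAGCTGCG
ActB_qPCR_R,239,CTGGATGGCTACGTACATGG
tRNA-Gly-GCC-1-1_cDNA_forward,382,GCATGGGTGGTTCAGTGG
tRNA-Gly-GCC-1-1_cDNA_reverse,383,TGCATGGGCCGGGAATCGAA
tRNA-Ile-AAU-1-1_forward,384,GGCCGGTTAGCTCAGTTG
tRNA-Ile-AAU-1-reverse,385,CCGTACGGGGATCGAA
Cox7c_mouse_F,360,CATGTTGGGCCAGAGTATC
Cox7c_mouse_R,361,AACCCAGATCCAAAGTACACG
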