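strain_id,isoform,direction,annealing_tm_c,primer_sequence,amplicon_size_bp
MIT9313,FtsH1,F,65,GCTCACAGGAGAGCAGCCGAGTAACG,178
MIT9313,FtsH1,R,65,GCGATTGTCGAGTTCGGGATCTACGG,178
MIT9313,FtsH2,F,63,CCTGGCACGACTGAGCGGGAGAC,226
MIT9313,FtsH2,R,63,CACCTGCCTGACGGGTTGGTTGAACAG,226
MIT9313,FtsH3,F,63,GCTTTTCAGCAGCTTCTTACCCAATCCTGC,208
MIT9313,FtsH3,R,63,CAAGCGTTGGGGCAGATCCATATCGAAG,208
MIT9313,FtsH4,F,65,CCTTTGCGCCCTTCAAGCAGAAACCCAC,214
MIT9313,FtsH4,R,65,TTCACCGTCAGAGAGGTATCAGCAGCC,214
MED4,FtsH1,F,63,TGATGGAGGTAGAAATGCTGTTATCGAAAC,157
MED4,FtsH1,R,63,TTTCACAGGGTGAACGTCAAAACTTATTCC,157
MED4,FtsH2,F,63,AAGCTGTTCAAGATAAAGAAGTTAGCAGGG,157
MED4,FtsH2,R,63,ACGGCTATATCTACATCATTCTCGGTTAGG,157
MED4,FtsH3,F,63,TTGGACTCGGAGCATTACTTTTATTCAGCA,173
MED4,FtsH3,R,63,GGCTCCCTCTTCTGCTCCATTCAGTTCG,173
MED4,FtsH4,F,63,AGCGGCCAATTCGTTTGCATCAG,203
MED4,FtsH4,R,63,CCTCTTTTAATTCTTCCGCGGCTTCAGG,203
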