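>vip3_synthetic synthetic VIP3-like mRNA stand-in (not At4g29830); ORF 1-873, 3'UTR follows
ATGACGCTGTTGGAACAGAAACCCGCGCAACGCCTTCCCCTAGAGCAAATCACGGTAATA
GAGGGACCGTCTTTTGGTAAGACAATGAAGGTTGAAGTCCGGAAGGCGGATGAACTTTGG
CTATTTTCAATGTCCACGAGGACCGGCAAAAAGATGATCTTTTGCAAACTAAGCAAAGCT
CGCATTGGAGGATTGCCAAAAGGTCCCAAGTTGCACACAAACACCAAGCCGTGTCTTAAC
GAGACGAAACAGGATCCCCAGAAAGTCGCGGTCGTCTATGACGATCCCGCCTTGGTAGAA
GATTTCATTAATTGGACCCATTCGGATTACGGAGAGGAGTTTGGAACCTCAAATCTGAAA
ATATGTGTGCAAAATTACTACGATGTAGTAGATCCTGAAGCTCCGAAGGGTACCAAGCCG
CCGAGCTTAGAATTCTGGGATCGCCCGGGTCGTGACGTGCACAAGGCTAAGATGGGGGCG
TCCCCTATTGCGTATATGTTTGGATCATTTATCTTGCTTGCTCATGGCCCCGGTACGGGC
GAAAATGCCAAGCGTGAGTCTTCAGCCGGGGCAGGGGAAGGAGGGGATTCTGCGCCATTT
AAAGATAGCTTTGTAGACCAGCAAATTTATGATAGGATGGAGTTTGCGTACAAGTCGTTC
TCTGTGATGCTTACGTCGCGAGTAGGCGTGGGTTACGCGGTTGATGATGCTATTGCCGTA
AGAGAGCATGACCAAATTTGGTCGGGGTTGCAAAACATTAAGCAACTAAAAGCCTGGGAG
CAACATAGATCTAATCAAGTTAGTATCCTGTCACTCCGGGAGCTGGCTGTGCAGTGGGAC
GCGTTAGCCGTGGCAAGGAATTCCCATGAATGAGCTGTCAGACCGGCTAACTGTGACTGC
ATGGGCGACGGCTGTAGAACCTTTCTCGATATCTTGGCGACGAGTTGGGGAAATTCGCTC
AGTAAGCTTACCACGCGGATTGAACTAGCCCCCTAAGCGTGTGTAGCACTTTGACATGGA
CACGTCCGCTGTGGAGGGTCAGGTCTAGCAGTAGC
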