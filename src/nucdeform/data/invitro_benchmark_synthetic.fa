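>pGUB_synth
TCGTATTTTAAGTTTAAGAATAGTCTTCTAATGGTGAAAAACCCGAGATTTATTCACAAAAACTCAATAA
AACCTCGCTTAACCCCACTTTTACTCCAGAAAAGTCTGCAATTATCCACCTTAAGTTTGTATTTTTCCAG
TAAAAGCCCATTTAACTAAACTGCGAGAATATGCCTGATCCGGTTTGATAAGTTAAGATACAGGGAACTT
TCCAGGGTCACAGATTTTAATCCCGATATAATTCCAGAATTTCCCGGATTTACTTTGATTAACTCTGGTA
AAGTTTCAATATTGTTTGCAATTTCTTGCATTTTTCTCAGAAAAGCTCGTTATTTCCTCGATATTGAAGT
TCCATGATAATCTTGAGCGATGTACACTCT
>nuc601_synth
GTAAAATATACATTTTTAGATACAATCAGGGAGGATTATTTCCCGTTATTTCCTCGAATAAATCTGTAAT
TCTTCCAATTAAGCCCAAATTTCCTCCAGATTTGCTCGGATTTACCCGATATAATTCTGATAAATCCCAT
AAAAAATTCAGTAAAATACAGAATTAAAACCACGTTATTATACGATTAATTGCCAATTTATCTAATAACA
ATCCTTCTAATTGTTCTTTTCCCTGCAAAAATCCCGTATTTCCTTGTAAAAAACCTGATAAAACTTGCAT
TTACTCCGATATTCCCCGCTTTTATTCGCGAATTGCTCGTTATTCTCTGTATTTTATCTGTATTTCAATG
TAGCAAGTAGTGATCATTCAAAGTTGCTAT
>fiveS_rDNA_A_synth
TTCAAGCGTAAGTGGTGACAAGTACACGTATGTTAATATTTCTCACGTATTTTCTGAAAAAATCCACTTT
TCCCCCATTAAAGCCCAAATAATCTCCAGTTTTCCTTGTTATTCCCCGTAATTTCTCCGCTTTTCCCCAT
TAAATATCTGTATTTTTCTTAGAGAGACTACTAACCGGCAAATTTTTAAGGATTACTGGGGAGTTCATGA
TACCATCTGGAAATCTAATTCTCCGGTTAAACCCCATATAATCTTGTAATTGGCCTGTAATTTCTTGAAT
AAGTTCTGTATTTACCTGTTAAAACCCATTATTTTCCCGCAAAAGCCCGCATAAGACCCGGTTAAGGAAG
ATTCCAAACCCGTCTCCTATATTAGAACCA
>fiveS_rDNA_B_synth
TCTAAAGGTGCGATTTTCTATCTTAATTGGGAGTTAAATTCCCTGTAATTTGCTCGAAATTTTTTGGTAT
TGCCCTGCTAAAGCCCGTTAAAATCCTGAAAAAACCTGATATTACTCAATTTTTACCCACTTTTCTCCGA
ATTTTTCCTGTAATTACCTCACATCTCAAACGTTAGGACTATACCGGGTATTGCGATATCGTCTGATCAT
CCCCATCGCTTACGTTAAAAATCTGAAATAAGTCTGCATTTACCCGTATTTGGCCCAAAATTGTCTGGAA
TTCCCTCAGAAAATTCCGTTAAAACCCGTGTTTTACCCGTATTTGCTCGATATTAGCTCGCTTTTTTTAT
CCTTCATGGTATTGACCCGAACTCTTCTCG
>chickenBG_synth
TGTTTTATCTATCGCTGGTGAAATATGTATTATTAAATAAACCTGCGATAAATCTGGATAAACCCAGTTT
TGCCCCGATTTTCCCCAGAATTTCCCTGGAAAAACCCGGAAAAACTCACTAAAAACCCGCATTTACTCAT
ATTTCTCCCATAAAAGAACATCTGAATATTTTTTAACACGTCATAAGTACACTAAACTAAATATCTCCCT
CAACAGCAAGTATTACTATTATTCATCTTAACCTCGTTATTGCCCAAAAAAAATCCATTAAACCCCAGTT
AACCTCTGCAATTCCCCACTTTTTCTCGAATAAAACCCACTAAACCCCAGTATTTCCCCGGAATTTCGTT
TTAGTTTTGTTGGCCTAGTTAAACCACCTG
>mmtvA_synth
GACTTAAACGCTAATTTTCGCATAGATTGTGGACCGTATTACTCGATAATTTCCCATATTTTCCCGAAAA
ATCCCCATTTTTACCCACAAAACCCCTGATTTTGTCTGTATTTCCCCACCATAATCCCAAAAAAGTTCAC
TTTTTCCCTGGTTAAAGACGTTAACAATGTGATGCGCAAGCGCTTACTTATACAATACGATGCTTTTCGT
AAGTCTGTCAAGTCTAATTTGCTCAATATTTCCTCGGAATTCCTTGGTTTTATCTTGTTAAAACCCAGAT
AACCCTCGATATTCCTTGATATTACCCACATTAAATCCAGATTTACCCGATTTTGTCCCGGTTTTAACCG
TTTGACCAGTTTTCGACTCCTCTTAGAGGT
>litAFN_synth
TACGTGTCAGACTTTTAGTTAAACTACAATCAAGATTAAATTCCAGTATAAATCCGCAAAAGTCCATATA
AACCTTGAAATTTCTCAATTTTCTCTCATTAAAACCCATTTAAATCCAGTTTAATCCTGCAAAACTCCGA
ATTTCACCCAAATAAAAGCTCAAAACAAGAATCTAGAAAAGTTAAAATTACTACATGGAGGGCACATCAT
ACCCTCTCGGTAAGAGTAAACCCTGCGATAAATCCGAAATTCCCCGGATTTAACTCAATTAAACCCAGAT
AAATCCCGTATTTTCTCACTATTACCTGTAAAAAACCTGAAATTGTCTGTTTAAAACTTGTATAAAATGC
GCTTGATGACATCAAACGCGAAGGCTACGA
>seaUrchin5S_synth
GCTTTAAGAAATCCTCACATTTGCTCGCTCTTGATCTTTTACCCACAAAAATCTCATAATTTCCCGAATA
AATCCTGGAATTGCCCAATTAAACCCCGCTTAAACCTGGTATTGTCCGACTAAATCTCACTTTTTCCCAA
TTTTCTCTTGCTTAACGTTGACACACTGGAATATTCGGGGTACTTATTTATTACTTAGCCCTTGCATAAT
TAAAGAAGTTTTATAATAAAATTCGCATTAATTCCAATATTACCCAAAAAATCCTTGATAAAGCCCGAAA
AACCCTCGTTTTTCCCTGTATAAACCCAAATTAAATTCGAAAAATCCCAATTTTCACTCGTATAATGGTT
AAAGCAGGAGAATACTATAACGAAACTAGT
>promoterX_synth
CTAGCGGGGAAAAGAAATACCTGCCTGCTAAGTTAAATAAACTCACAAAAATCCCAGTTTTTCCCATAAA
ACGCCCGGTTTTGCCCGATATTTCCCTGTTAAATCTCATATAAACCCGCATATTTTCCGATTAACTCCAA
TATTTACTCAAATTTAAGATCATTATTCAATTGATACAAACCGTGTCGCGATGGTTCATAAATCACACGT
CTGTATAACAACTGGGAATTGCCTGTAATAATCCTGCAATTTTTCGGATAACACCTGGAATTACCCAATT
TTGCCCCGCTTAACCTCGAATTTTCCCAGTATAATCCCAATTAAATTCAATAAAACCTTGTTTAATTTCT
CTGAGCTGTATGTCGTATTTGGACATTCAA
>telomericY_synth
CTATTCTTACCTCCACCCATTGTGTCATCCCAGAGAATTTTCTTGTCTTAAACTCAAAATTATCCATTTA
ACTCTCGGAATTTCCCAAATAAACTTCATTTTTACCCATATTTTCTCAGCAATTCCTCGGTTAAACCCGA
TAAATATTTGAATTTAGGAACGCGAAAAAAGATGTTTAAGAAATTAGGCAATTCTTCATGCACAGAGCGT
TTCTACCTTAAACGAATTAATTCCGAGAAAAACCTGTATTTACTCAAATAATGCCCGTAATTGCCCGTAT
AAGTCTCGAATAAGCCCGTATTTACCCAAAATTTCTCTGATATTTCTTGGTAAATACCCAGTAAATATAC
AATGGTAACAAACAATTGTAATTGTTTTAA
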