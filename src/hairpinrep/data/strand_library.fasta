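>0A
GCAGCGTTAATTCCCGCGCCTATCGGGAATGTAACGCAGTGGGTAATAATGACGATAGCCGTTCGGGAAAAGCGAACGGTATCG
>0B
GCAGCGATACCGTTCGCTTTTCCCGAACGGCTATCGCAGTGGGTAATAATGAGCGAACTGTCGGTGCTTGCGACAGTGTCGC
>0C
GCAGGCGACACTGTCGCAAGCACCGACAGTTCGCCAGTGGGTAATAATGAGCGGTTCCTTGCGGAGTAGGCAAGGAATCCGC
>0D
GCAGGCGGATTCCTTGCCTACTCCGCAAGGAATCGCCAGTGGGTAATAATGACGTTACATTCCCGATAGGCGCGGGAATTAACG
>0A*
GCTGCGCATTAACGCGCTTGTCCCGCGTTAATTGCGCTCATTATTACCCACTCGCTCTCGGCTGTTTTGCCCAGCCGAGCAGCG
>0B*
GCTGCGTTGCATTGGCGATCAAAGCCAATGCGAACGCTCATTATTACCCACTCGCAATTAACGCGGGACAAGCGCGTTAATGCG
>0C*
GCTGGTTGGAGAAGGCGAACAGCACGCCTTCCCAACCTCATTATTACCCACTCGTTCGCATTGGCTTTGATCGCCAATGCAACG
>0D*
GCTGCGCTGCTCGGCTGGGCAAAACAGCCGAGAGCGCTCATTATTACCCACTGTTGGGAAGGCGTGCTGTTCGCCTTCTCCAAC
>1A
GCAGCGTTAATTCCCGCGCCTATCGGGAATGTAACGCAAAAGAAGAGAAAGACGATAGCCGTTCGGGAAAAGCGAACGGTATCG
>1B
GCAGCGATACCGTTCGCTTTTCCCGAACGGCTATCGCAAAAGAAGAGAAAGAGCGAACTGTCGGTGCTTGCGACAGTGTCGC
>1C
GCAGGCGACACTGTCGCAAGCACCGACAGTTCGCCAAAAGAAGAGAAAGAGCGGTTCCTTGCGGAGTAGGCAAGGAATCCGC
>1D
GCAGGCGGATTCCTTGCCTACTCCGCAAGGAATCGCCAAAAGAAGAGAAAGACGTTACATTCCCGATAGGCGCGGGAATTAACG
>1A*
GCTGCGCATTAACGCGCTTGTCCCGCGTTAATTGCGCTCTTTCTCTTCTTTTCGCTCTCGGCTGTTTTGCCCAGCCGAGCAGCG
>1B*
GCTGCGTTGCATTGGCGATCAAAGCCAATGCGAACGCTCTTTCTCTTCTTTTCGCAATTAACGCGGGACAAGCGCGTTAATGCG
>1C*
GCTGGTTGGAGAAGGCGAACAGCACGCCTTCCCAACCTCTTTCTCTTCTTTTCGTTCGCATTGGCTTTGATCGCCAATGCAACG
>1D*
GCTGCGCTGCTCGGCTGGGCAAAACAGCCGAGAGCGCTCTTTCTCTTCTTTTGTTGGGAAGGCGTGCTGTTCGCCTTCTCCAAC
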