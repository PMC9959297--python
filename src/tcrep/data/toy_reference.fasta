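>TRAV1
GTCATGAGGATGGCTCACATTCGCCCAGGCTTCAGTGAAGTCTATAAGCTCCTTAGATCC
GCGAAGAATTGGCTACGCTGT
>TRAV1-1
CGGTGCTCACCCAACTGGGGAGTAGCCCTGTCAATTTCGCCCAAGTCTGTCAGAGCGCGC
GATAGTTATTTGGATCACTGT
>TRAV1-2
TTCCATGCGCGACGTGAAGAAATGCATGTGCGAACTAAGCTCGAGTTCACCGATCGGCGC
GGCCCACGGCATTCGTGTAGT
>TRAV11
GGCAATATAACGGCTTTGCCCGATCACTTCCGGCTGATATGCAGTAAAACCGCCTACAGC
TTACTAGCCCAAGAATGTGTA
>TRAV11D
GCCTCACTGGGATTCTTTGCATGCATATCGGTCGCCGTGGCTGCACGACCAGCACCCCTT
TACAATCAGATTTGTGTGGTG
>TRAV14-1
TTAAGGATTTACCATCGTGCCAGAATGCCAGCACCGGTTCGCTTTCACAATAGAGAGGCC
TACATCACAGCATCAGTTTGT
>TRAV1D-1
GAGATTGGGAGCGCGAACTCACCGATTCCACGAACCCGTCCATGTTCCTGCGGTAGCGAG
CGGCAGTTCCGGCCCTGTACA
>TRAV7D-2
AAGGGGGTTTTTGACTCCTGTACCCGTACCATGGAGCATCGTCGGAGGCTGTCCTACCTC
CTCATTGGCTGGTATACCTGT
>TRAJ18
GATAGAGGAAGCGCCCTGGGAAGACTCCACTTTGGTTCTCATGCGCAA
>TRAJ2
CTTGACACGAACTTTTTTGGTGTTTTCGCGTTGAGAACGCAACTGTCA
>TRAJ3
GCGATAGTCTTTGGTTCACGAATTATTTTTCCTAGTGTGCCTTCCATA
>TRAJ4
TGGAGTACCTTTGGTCGACTTGTCTCTTGGCTTGCTGTCCTGTCACAC
>TRAJ5
GGACATTTGTACAATTTTGGTTCGCGCTGCCAAAGTTTGCTCGCCTGC
>TRAJ6
GACCTACTCGGAACCGGATTTGGTCCTGGACCCTGTCCTGTGATACGA
>TRBV1
CCGTTCCACGATAACCACTACAGCTGGAAAGGTGGAATGTCTCCGCTTCCTCGCGTTATT
ACATGCCGCCCTGGATGTTCC
>TRBV2
GGAAGAAGTAGACACCCTATTCGAGCTATAGGGTGGCCTGATCCTAGGGTCGATACAAGC
AAAATACAGTGTCAGTGTCCG
>TRBV3
CGGCAGTGCACCGCCACGCCCACCGGTTCAAGGAGGCAGCGGTGTAGGCGGCAGAGGGGT
TTGGGATACAGATCTTGTTCG
>TRBV4
ACTGTTTGTGTTCGCCCAGCGTGGCGGCCATCCTTCCTCAACCGTCGCACCACGGGGCCT
AGTGTTCTAGTTTCGTGTATA
>TRBV5
GGCTATTATGTTGTGAGTCAGCACCTCCTTGTTTACACCCGAATGTATCCCTCCACGGGA
AGCCACGTAGTAAAGTGTAGG
>TRBJ1-1
CGTGTCGGTGTTTTTGGTGAACGGCGCCCGAGTGCCCCGGAGAGGATC
>TRBJ1-2
AGAACTCTTGCATCTTTTGGTGCGAGGCCAATCGTTCTACTTCACGCT
>TRBJ1-3
TGCTCATCTATCGTCCCTTTTGGTCCTTTCAGATTATGTCACCTAGCC
>TRBJ2-7
GTCACTAACTTTGGTGCAGAGCGGAGGCGAGGTGCTCGTCTTTCCCAT
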