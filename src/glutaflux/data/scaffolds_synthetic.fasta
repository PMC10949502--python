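>MicC synthetic stand-in scaffold (NOT the E. coli MicC sequence; replace via user FASTA for construct design)
TTTCTGTTGGGCCATTGCATTGCCACTGATTTTCCAACATATAAAAAGACAAGCCCGAAC
AGTCGTCCGGGCTTTTTTT
>DsrA synthetic stand-in scaffold (NOT the E. coli DsrA sequence; replace via user FASTA for construct design)
AACGAATTTTTTAAGTGCTTCTTGCTTAAGCAAGTTTCATCCCGACCCCCTCAGGGTCGG
GATTT
>MicF synthetic stand-in scaffold (NOT the E. coli MicF sequence; replace via user FASTA for construct design)
GCTATCATCATTAACTTTATTTATTACCGTCATTCATTTCTGAATGTCTGTTTACCCCTA
TTTCAACCGGATG
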