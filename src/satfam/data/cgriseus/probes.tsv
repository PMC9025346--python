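no	tr_family	sequence
1	33A	GTGATGTCACCTGAAGGGTCT
2	79A	CTAGTTTTCTGTATTACGTTGTATCCG
3	25B	TGTCCTTCTCTCCCCAGTGTC
4	72A	CCTCCTAAAGACATAACTGAAATCC
5	77A	CCTTGCCTTGCCTAAATGAGA
6	84A	ACTGGAGAGAAACCCTATGAATACC
7	26A	CTAGTGCTCCTGTAAGGAAGCC
8	25A	GAAGAACCAGCTAACACTAGGC
9	27A	AGGCTGGGACAATGGAGA
10	62A	CAGCACTGTGACATCAGAATAGA
11	18A	GACAGATGAGAGCTGGGTGA
12	24B	TGGTCAGGCCTATACAGAGAG
13	13A	GTGCAGAGTGAGAGTGCAGAGAG
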