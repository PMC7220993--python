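locus	forward	reverse	locus_size	scheme	mlst2019
ALA1	GCTCTTCGTGAGGTTCTTGG	ACCTCGTAGGCATCAGTGCT	424	MLST2013	1
CDC19	CGCCAGTCAGAGAAGGAATA	GTCGACCTGGTTCTTGACAC	355	MLST2013	1
ERG10	AACACAACATTTCCCGTGAG	AGAGCTTAGCGTCAGCACTGA	652	MLST2013	0
GLN4	TGTTCTCAGAGGGTTTCCTG	CCACATCTGAGGATTGTCGT	558	MLST2013	1
PGI1	ACCGCTGAGACTCTTCGCAA	CTCCATGGAAAGCTGCTGGA	472	MLST2013	1
PGM2	GAACGGTGTCTACGGTCTTG	TCAATGTACAGACGGATGGTC	548	MLST2013	1
NUP116	ACCGCTACAACTGGATTTGG	GAGACCTGTTTGAGGGCTTG	425	MLST2017	0
URA1	CAAGCCAATTGTGCTGAGAA	GGTGTCGTAGGGCAGTTGAT	465	MLST2017	0
URA3	GCCAAAAAGACCAACCTGTG	CCTCATCCATACGGTTCTGC	470	MLST2017	0
SAPT4	ATCATTAACACCCCGGCATA	GTGTCACCAAGCAGAGCAAA	501	MLST2017	1
PLB3	AAGAATATCTGGGATCTTTC	TGAAGAAGAAGTACCAAGAA	393	MLST2017	0
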