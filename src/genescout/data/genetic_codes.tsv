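# NCBI genetic code tables: table_id<TAB>64 amino acids (TCAG codon order)<TAB>start codons
# codon order: TTT TTC TTA TTG TCT ... GGG
1	FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	TTG,CTG,ATG
2	FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSS**VVVVAAAADDEEGGGG	ATT,ATC,ATA,ATG,GTG
4	FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	TTA,TTG,CTG,ATT,ATC,ATA,ATG,GTG
5	FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSSSSVVVVAAAADDEEGGGG	TTG,ATT,ATC,ATA,ATG,GTG
9	FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNNKSSSSVVVVAAAADDEEGGGG	ATG,GTG
11	FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG	TTG,CTG,ATT,ATC,ATA,ATG,GTG
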