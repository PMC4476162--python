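AAAGGG
ATGAGT
GCGGTA
ATCGGA
TATCTT
GGAAAA
AGGGAT
CCGAGA
GTAAAA
AGGAGG
AACATA
GCCAGA
GGCAGT
GACAAG
GGACTA
AACGAG
CATGAT
ACGGGA
GGAGGG
AGATGC
GGGCGG
GAGTGG
ATGAGA
TTGGAA
ACAACA
ACAAGG
AGGAAA
TACGCA
AATAGG
AAAGAG
ATGACA
GAAAGG
TCGATA
AAATGG
GAAAAG
CAGCGC
CGGGAT
AGATAT
AGTGAT
ACTAGA
AGATCG
GGAAAG
CTAGGA
AGCGGA
CGAAAG
GGGAAG
GCAAAG
AAAGGA
TTAGGG
AGAAGA
AACGGA
GAACAT
CTGATA
CTTAGG
GGAATA
AAAGAC
CGCGGG
GTGCAG
GAAGAA
GACGAG
AAGAGG
GATTCA
CGGAAA
GGAAGG
AGGACT
GCATGG
AAGAGA
CATAAA
AAAAGA
GAAAAT
AGAAAA
CAAAAA
AGGAGA
GGCGCA
CGGGGG
GATAGA
TACGAA
CATGGT
GAGAGG
ACGTGG
CACGAC
TGGGGG
ACGGAG
AAGGTA
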