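>CTCF6F forward primer, bisulfite-converted ICR1 CTCF site 6
GTATAGTATATGGGTATTTTTGGAGG
>CTCF6R reverse primer, bisulfite-converted ICR1 CTCF site 6
CCCAATTAAAACRAACTCRAACTATAAT
>CTCF6M hydrolysis probe, methylated allele (FAM)
AAGTGGTCGCGCGGCGGTAGTGTA
>CTCF6U hydrolysis probe, unmethylated allele (HEX)
TGGAAGTGGTTGTGTGGTGGTAGTGTAGG
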