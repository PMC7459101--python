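# GRCh38 chromosome lengths and approximate centromere midpoints (bp) for
# the chromosomes carrying the FISH locus panel.
chromosome	length_bp	centromere_bp
chr1	248956422	123400000
chr2	242193529	93900000
chr11	135086622	53400000
chr12	133275309	35500000
chr16	90338345	36800000
chr17	83257441	25100000
chrX	156040895	60600000
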