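# Panel of myogenic loci analysed by 3D FISH, with approximate GRCh38 gene
# coordinates (~0.1 Mbp precision; only Mbp-scale gene-centromere distances
# are consumed downstream). BED-like: 0-based half-open start/end.
# window_mbp is the default K_mean neighbourhood span for that gene.
chromosome	start_bp	end_bp	gene_symbol	window_mbp	probe_id
chr17	10520000	10550000	MYH2	0.95	MYH2
chr1	100719000	100739000	VCAM1	0.95	VCAM1
chr1	203083000	203086000	MYOG	0.95	MYOG
chr11	112961000	113278000	NCAM1	0.95	NCAM1
chr11	66546000	66563000	ACTN3	0.95	ACTN3
chr2	161992000	162074000	DPP4	0.95	DPP4
chr2	219418000	219427000	DES	0.95	DES
chr1	236686000	236764000	ACTN2	1.5	ACTN2
chrX	134460000	134501000	HPRT1	1.5	HPRT1
chr12	80707000	80710000	MYF5	1.5	MYF5
chr12	80716000	80719000	MYF6	1.5	MYF6
chr16	89172000	89197000	CDH15	1.0	CDH15
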