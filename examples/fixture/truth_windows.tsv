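genome_id	protein_id	start	window	motif_id
g00000	g00000|p0000	93	MEVGWYRSPFSRVVHLYRNGK	YR..F.RV.
g00002	g00002|p0000	71	TTLSFYRPPFLRVRRPFYIIF	YR..F.RV.
g00002	g00002|p0005	13	SRWVWYRLCFTYVHRGRGSYY	YR..F..V.
g00002	g00002|p0008	1	WRNWCYRLSFCRVDFIPSCWS	YR..F.RV.
g00001	g00001|p0001	12	HENNGYRQTFRRAESMPNPHR	YR..F.R..
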