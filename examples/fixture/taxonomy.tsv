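genome_id	lineage	phylum
g00000	d__Bacteria;p__Bacillota;c__;o__;f__;g__Bacillota_gen;s__Bacillota sp0000	Bacillota
g00001	d__Bacteria;p__Bacteroidota;c__;o__;f__;g__Bacteroidota_gen;s__Bacteroidota sp0000	Bacteroidota
g00002	d__Bacteria;p__Verrucomicrobiota;c__Verrucomicrobiae;o__Verrucomicrobiales;f__Akkermansiaceae;g__Akkermansia;s__Akkermansia muciniphila	Verrucomicrobiota
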