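candidate_id	mhc_template	peptide_plddt	inter_pae
lig_00000:00	1muj	93.838	3.94
lig_00000:01	4p23	87.639	10.56
lig_00000:02	1muj	82.279	7.926
lig_00000:03	1muj	76.197	7.881
lig_00000:04	4p23	84.209	2.137
lig_00000:05	4p23	84.691	7.676
lig_00000:06	4p23	94.046	3.04
lig_00000:07	4p23	96.743	3.063
lig_00000:08	6mng	92.665	10.726
lig_00000:09	6mng	94.253	3.451
lig_00000:10	4p23	63.288	3.364
lig_00001:00	6mng	83.647	2.272
lig_00001:01	4p23	97.134	3.154
lig_00001:02	6mng	76.269	5.44
lig_00001:03	4p23	94.151	5.306
lig_00001:04	6mng	93.267	10.554
lig_00001:05	4p23	68.308	10.375
lig_00001:06	1muj	97.885	10.376
lig_00001:07	1muj	94.913	2.958
lig_00001:08	4p23	93.589	3.862
lig_00001:09	4p23	95.868	2.13
lig_00001:10	1muj	94.974	2.161
lig_00002:00	6mng	96.243	2.078
lig_00002:01	1muj	92.076	9.208
lig_00002:02	1muj	75.846	3.683
lig_00002:03	6mng	61.354	3.138
lig_00002:04	4p23	97.706	2.459
lig_00002:05	4p23	94.872	3.652
lig_00002:06	1muj	76.386	2.782
lig_00002:07	1muj	80.044	5.064
lig_00002:08	4p23	92.471	2.563
lig_00002:09	6mng	83.243	9.173
lig_00002:10	6mng	94.7	3.204
lig_00003:00	1muj	97.623	3.099
lig_00003:01	6mng	92.81	3.755
lig_00003:02	4p23	95.062	11.111
lig_00003:03	1muj	94.858	10.123
lig_00003:04	1muj	60.413	10.344
lig_00003:05	6mng	65.115	6.755
lig_00003:06	4p23	61.401	7.671
lig_00003:07	1muj	79.567	3.178
lig_00003:08	1muj	97.317	2.673
lig_00003:09	4p23	80.422	2.961
lig_00003:10	6mng	94.059	2.487
lig_00004:00	4p23	94.119	3.26
lig_00004:01	1muj	97.955	2.775
lig_00004:02	6mng	96.457	3.292
lig_00004:03	6mng	94.648	7.277
lig_00004:04	4p23	95.705	11.996
lig_00004:05	6mng	76.836	7.555
lig_00004:06	6mng	97.987	3.608
lig_00004:07	6mng	85.426	10.516
lig_00004:08	4p23	87.024	3.858
lig_00004:09	1muj	73.737	2.665
lig_00004:10	6mng	73.016	2.42
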