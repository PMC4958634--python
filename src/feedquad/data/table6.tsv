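category	go_id	K_ref	k_cnv	expected	fold_enrichment	p_bonferroni
Response to interferon-gamma	GO:0034341	44	4	0.1	NA	0.0008
Antigen processing and presentation of peptide or polysaccharide antigen via mhc class ii	GO:0002504	36	3	0.08	NA	0.02
Macrophage activation	GO:0042116	164	5	0.38	NA	0.009
Immune system process	GO:0002376	1477	12	3.42	3.8	0.005
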