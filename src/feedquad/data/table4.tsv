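category	K_ref	k_deg	expected	fold_enrichment	p_value
Biological regulation	3868	169	141.9	1.19	7.27E-03
Regulation of biological process	2803	126	102.83	1.23	9.21E-03
Death	595	32	21.83	1.47	2.24E-02
Cell death	591	32	21.68	1.48	2.07E-02
Apoptotic process	577	32	21.17	1.51	1.54E-02
Negative regulation of apoptotic process	93	10	3.41	2.93	2.70E-03
Protein folding	154	14	5.65	2.48	2.05E-03
Cell communication	3113	134	114.2	1.17	2.64E-02
Immune system process	1477	68	54.18	1.25	3.32E-02
Neurological system process	1234	57	45.27	1.26	4.60E-02
Regulation of transcription from RNA polymerase II promoter	1137	53	41.71	1.27	4.65E-02
Response to stress	704	39	25.83	1.51	8.18E-03
RNA metabolic process	2109	92	77.37	1.19	4.72E-02
RNA splicing	137	11	5.03	2.19	1.39E-02
RNA splicing, via transesterification reactions	134	10	4.92	2.03	2.84E-02
Unclassified	7560	238	277.34	0.86	1.40E-03
Cellular component morphogenesis	462	10	16.95	0.59	4.84E-02
DNA replication	167	1	6.13	NA	1.53E-02
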