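gene	flagged	qpcr_HH	qpcr_HL	qpcr_LL	qpcr_LH	array_HH	array_HL	array_LL	array_LH
PPAP2C	0	0.064	-0.205	-0.331	-0.209	7.392	7.331	7.106	6.974
CREM	0	0.09	-0.0991	-0.0142	-0.0238	8.565	8.258	9.270	8.379
DNAJC5	1	-0.0515	-0.0371	0.0322	0.0441	10.624	10.609	9.999	10.097
BAG3	1	-0.145	-0.312	0.338	-0.196	9.749	9.474	10.929	9.237
DNAJB1	1	0.524	0.563	0.975	0.525	12.184	12.210	14.027	12.255
HADHB	0	-0.0211	-0.055	-0.0841	-0.0789	11.741	11.333	11.329	11.371
SCN4B	1	-0.336	-0.378	0.127	-0.173	7.712	7.398	7.946	7.638
GBP7	1	-0.102	0.0171	0.0443	-0.00681	9.982	11.177	10.324	10.111
HSPH1	1	-0.0486	-0.172	0.409	-0.175	12.823	12.443	15.450	12.164
KCNMA1	0	0.15	-0.0231	-0.0193	0.23	7.806	7.218	7.553	8.201
LPIN1	0	-0.0992	-0.118	-0.121	-0.0345	9.393	9.310	10.114	9.404
SIRT6	0	0.11	0.0874	0.0579	0.0931	9.313	9.593	9.250	9.500
TSHZ2	0	0.102	-0.0294	-0.0895	0.0511	9.651	9.347	8.737	9.733
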