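genome_id	genome_size_bp	cds_count	trna_count	gc_percent	integrase
AS7	41572	53	0	57	no
51	43551	84	0	55	low_confidence
56	43551	84	0	55	low_confidence
59.1	46057	87	0	54	yes
3	46349	83	0	57	yes
Asp37	47977	83	0	57	yes
32	48252	83	0	57	yes
Aes508	160646	230	10	41	no
25	161475	232	11	41	no
AS4	163875	268	15	41	no
44RR2.8t.2	173590	253	16	44	no
31.2	172957	245	16	44	no
SW69-9	173097	249	16	44	no
L9-6	173578	251	16	44	no
Riv-10	174311	249	16	44	no
PX29	222006	322	24	42	no
AS5	225268	333	25	43	no
65.2	236567	410	18	37	no
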