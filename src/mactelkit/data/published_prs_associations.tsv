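trait	beta	or_printed	ci_low_printed	ci_high_printed	p_fdr	rounding_self_consistent
Serine	-0.65	0.52	0.46	0.58	8.38e-28	1
Glycine	-0.58	0.56	0.50	0.63	5.44e-19	1
Lysophosphatidylcholine acyl C14:0	0.21	1.23	1.11	1.37	2.48e-03	1
Phosphatidylcholine diacyl C32:1	0.21	1.23	1.11	1.37	2.48e-03	1
Phosphatidylcholine diacyl C34:1	0.21	1.23	1.11	1.37	2.48e-03	1
Phosphatidylcholine acyl-alkyl C38:1	0.20	1.22	1.10	1.36	2.97e-03	1
Arginine	0.17	1.18	1.07	1.31	2.83e-02	0
Phenylalanine	-0.17	0.85	0.76	0.94	2.85e-02	0
Arteriolar retinal calibre	0.32	1.38	1.25	1.52	2.22e-10	1
Venular retinal calibre	0.18	1.19	1.08	1.32	7.00e-04	0
T2D	0.17	1.19	1.07	1.33	7.72e-04	1
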