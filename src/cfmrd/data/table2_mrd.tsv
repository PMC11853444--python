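subject_id	day	compartment	n_mutations	gm_vaf	status	gene_level
001	pre	BM	3	4.58	ok	1
001	pre	plasma	2	20.92	ok	1
001	28	plasma	5	0.1	ok	0
001	56	plasma	3	0.51	ok	0
001	84	plasma			ND	1
001	84	BM			ND	1
002	pre	BM	2	34.42	ok	1
002	pre	plasma	2	42.72	ok	1
002	28	plasma	3	2.4	ok	0
002	56	plasma	3	4.02	ok	0
002	84	plasma	3	2.77	ok	1
002	84	BM	2	1.13	ok	1
003	pre	BM	2	11.04	ok	1
003	pre	plasma	0		ok	1
003	28	plasma	0		ok	0
003	56	plasma	1	2.31	ok	0
003	84	plasma	0		ok	1
003	84	BM	0		ok	1
004	pre	BM	1	44.48	ok	1
004	pre	plasma	1	44.87	ok	1
004	28	plasma	1	0.5	ok	0
004	56	plasma	1	0.26	ok	0
004	84	plasma	0		ok	1
004	84	BM	1	0.28	ok	1
005	pre	BM	5	3.54	ok	1
005	pre	plasma	16	0.97	ok	1
005	28	plasma	2	0.54	ok	0
005	56	plasma	2	0.30	ok	0
005	84	plasma	2	0.34	ok	1
005	84	BM	5	0.37	ok	1
006	pre	BM	4	37.62	ok	1
006	pre	plasma	4	35.91	ok	1
006	28	plasma	0		ok	0
006	56	plasma	0		ok	0
006	84	plasma	2	0.11	ok	1
006	84	BM	1	2.55	ok	1
007	pre	BM	8	22.97	ok	1
007	pre	plasma	9	18.72	ok	1
007	28	plasma	1	0.66	ok	0
007	56	plasma	6	1.07	ok	0
007	84	plasma	7	1.52	ok	1
007	84	BM	10	4.29	ok	1
008	pre	BM	0		ok	1
008	pre	plasma	0		ok	1
008	28	plasma	0		ok	0
008	56	plasma	0		ok	0
008	84	plasma	0		ok	1
008	84	BM	0		ok	1
009	pre	BM	2	0.66	ok	1
009	pre	plasma	6	0.84	ok	1
009	28	plasma	0		ok	0
009	56	plasma	0		ok	0
009	84	plasma	7	0.9	ok	1
009	84	BM	4	0.24	ok	1
010	pre	BM	3	8.14	ok	1
010	pre	plasma	3	23.98	ok	1
010	28	plasma	3	0.64	ok	0
010	56	plasma	2	19.28	ok	0
010	84	plasma	2	33.48	ok	1
010	84	BM	4	5.92	ok	1
011	pre	BM	3	19.83	ok	1
011	pre	plasma	3	9.66	ok	1
011	28	plasma	1	1.59	ok	0
011	56	plasma	1	3.40	ok	0
011	84	plasma	1	6.32	ok	1
011	84	BM	0		ok	1
012	pre	BM	4	7.67	ok	1
012	pre	plasma	11	5.68	ok	1
012	28	plasma	5	0.62	ok	0
012	56	plasma	3	0.04	ok	0
012	84	plasma	7	0.36	ok	1
012	84	BM	4	0.46	ok	1
013	pre	BM	1	48.78	ok	1
013	pre	plasma	5	2.50	ok	1
013	28	plasma	1	0.26	ok	0
013	56	plasma	2	1.63	ok	0
013	84	plasma	2	1.60	ok	1
013	84	BM	2	4.23	ok	1
015	pre	BM	0		ok	1
015	pre	plasma	0		ok	1
015	28	plasma	1	36.07	ok	0
015	56	plasma	1	30.3	ok	0
015	84	plasma	1	31.2	ok	1
015	84	BM	2	0.94	ok	1
016	pre	BM	1	33.18	ok	1
016	pre	plasma	5	1.46	ok	1
016	28	plasma	1	0.98	ok	0
016	56	plasma	1	0.03	ok	0
016	84	plasma	1	0.06	ok	1
016	84	BM	0		ok	1
017	pre	BM	1	6.66	ok	1
017	pre	plasma	3	3.78	ok	1
017	28	plasma	0		ok	0
017	56	plasma	1	0.21	ok	0
017	84	plasma	0		ok	1
017	84	BM	0		ok	1
018	pre	BM	6	1.42	ok	1
018	pre	plasma	8	0.63	ok	1
018	28	plasma	2	0.57	ok	0
018	56	plasma	0		ok	0
018	84	plasma	0		ok	1
018	84	BM			ND	1
019	pre	BM	9	5.79	ok	1
019	pre	plasma	6	9.43	ok	1
019	28	plasma	3	0.18	ok	0
019	56	plasma	5	0.54	ok	0
019	84	plasma	2	0.23	ok	1
019	84	BM	1	0.06	ok	1
020	pre	BM	5	4.11	ok	1
020	pre	plasma	7	1.71	ok	1
020	28	plasma	1	0.97	ok	0
020	56	plasma	1	0.37	ok	0
020	84	plasma	0		ok	1
020	84	BM	1	0.37	ok	1
021	pre	BM	2	0.69	ok	1
021	pre	plasma	4	1.20	ok	1
021	28	plasma	0		ok	0
021	56	plasma	1	0.11	ok	0
021	84	plasma	1	0.11	ok	1
021	84	BM	0		ok	1
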