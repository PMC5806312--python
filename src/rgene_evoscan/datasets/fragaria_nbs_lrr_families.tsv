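family_id	supergroup	ka_ks_mean	omega_m0	two_delta_ln	lr_flag	n_exchange_events
TNL_family0	TNL	0.60	0.23	0.00	ns	0
TNL_family1	TNL	0.62	0.67	45.74	**	18
TNL_family2	TNL	0.77	NA	NA	NA	0
TNL_family3	TNL	0.65	0.73	40.23	**	15
TNL_family4	TNL	0.37	0.38	0.54	ns	1
TNL_family5	TNL	0.73	1.01	110.93	**	14
TNL_family6	TNL	0.41	0.35	1.38	ns	0
TNL_family7	TNL	0.54	0.54	44.13	**	9
TNL_family8	TNL	0.96	NA	NA	NA	0
TNL_family9	TNL	0.62	0.49	47.84	**	29
TNL_family10	TNL	0.75	NA	NA	NA	0
TNL_family11	TNL	0.57	0.58	14.81	**	5
TNL_family12	TNL	0.89	NA	NA	NA	0
TNL_family13	TNL	0.77	0.77	299.48	**	2
TNL_family14	TNL	0.51	0.49	101.49	**	5
TNL_family15	TNL	0.59	0.61	25.08	**	2
TNL_family16	TNL	0.22	NA	NA	NA	0
TNL_family17	TNL	0.85	0.85	9.70	**	4
TNL_family18	TNL	0.79	NA	NA	NA	0
TNL_family19	TNL	0.35	0.33	3.78	ns	8
TNL_family20	TNL	0.47	0.42	8.82	*	7
TNL_family21	TNL	0.78	NA	NA	NA	0
TNL_family22	TNL	0.28	0.30	0.00	ns	1
TNL_family23	TNL	0.56	0.54	27.06	**	6
TNL_family24	TNL	0.51	0.45	4.64	ns	3
TNL_family25	TNL	0.59	0.63	81.98	**	4
TNL_family26	TNL	0.55	NA	NA	NA	0
TNL_family27	TNL	0.67	0.61	28.33	**	4
TNL_family28	TNL	0.58	NA	NA	NA	0
TNL_family29	TNL	0.63	NA	NA	NA	0
TNL_family30	TNL	0.71	NA	NA	NA	0
TNL_family31	TNL	0.54	NA	NA	NA	0
TNL_family32	TNL	0.71	0.62	80.84	**	3
TNL_family33	TNL	0.41	NA	NA	NA	0
TNL_family34	TNL	0.41	0.43	2.73	ns	0
TNL_family35	TNL	0.88	NA	NA	NA	0
TNL_family36	TNL	0.26	0.15	0.00	ns	0
TNL_family37	TNL	0.60	NA	NA	NA	0
non-TNL_family0	non-TNL	0.45	0.42	35.48	**	11
non-TNL_family1	non-TNL	0.78	0.83	59.37	**	28
non-TNL_family2	non-TNL	0.59	0.59	75.22	**	39
non-TNL_family3	non-TNL	1.46	0.99	43.01	**	0
non-TNL_family4	non-TNL	0.64	0.72	4.67	ns	10
non-TNL_family5	non-TNL	0.93	NA	NA	NA	0
non-TNL_family6	non-TNL	0.83	0.93	72.76	**	11
non-TNL_family7	non-TNL	0.58	0.68	73.55	**	10
non-TNL_family8	non-TNL	0.69	0.49	27.03	**	63
non-TNL_family9	non-TNL	0.63	0.54	15.19	**	5
non-TNL_family10	non-TNL	0.60	0.36	10.98	**	12
non-TNL_family11	non-TNL	0.91	0.97	62.72	**	5
non-TNL_family12	non-TNL	0.67	NA	NA	NA	0
non-TNL_family13	non-TNL	0.82	0.87	146.39	**	77
non-TNL_family14	non-TNL	1.14	NA	NA	NA	0
non-TNL_family15	non-TNL	0.42	0.40	0.19	ns	4
non-TNL_family16	non-TNL	0.41	NA	NA	NA	0
non-TNL_family17	non-TNL	NA	NA	NA	NA	0
non-TNL_family18	non-TNL	0.51	0.43	0.00	ns	0
non-TNL_family19	non-TNL	0.65	0.65	37.48	**	3
non-TNL_family20	non-TNL	0.79	0.93	129.67	**	5
non-TNL_family21	non-TNL	0.74	0.92	10.52	**	4
non-TNL_family22	non-TNL	0.68	0.58	25.75	**	119
non-TNL_family23	non-TNL	0.64	0.58	47.88	**	2
non-TNL_family24	non-TNL	0.45	0.50	23.82	**	4
non-TNL_family25	non-TNL	0.58	0.54	111.42	**	8
non-TNL_family26	non-TNL	0.57	0.59	74.25	**	18
non-TNL_family27	non-TNL	1.00	1.09	116.83	**	26
non-TNL_family28	non-TNL	0.72	0.62	18.65	**	0
non-TNL_family29	non-TNL	0.92	NA	NA	NA	0
non-TNL_family30	non-TNL	0.94	NA	NA	NA	0
non-TNL_family31	non-TNL	0.73	NA	NA	NA	0
non-TNL_family32	non-TNL	0.96	0.87	47.42	**	16
non-TNL_family33	non-TNL	1.06	0.95	98.69	**	8
non-TNL_family34	non-TNL	0.71	0.44	1.14	ns	1
non-TNL_family35	non-TNL	0.62	NA	NA	NA	0
non-TNL_family36	non-TNL	0.93	NA	NA	NA	0
non-TNL_family37	non-TNL	0.65	NA	NA	NA	0
non-TNL_family38	non-TNL	0.54	0.50	0.00	ns	1
non-TNL_family39	non-TNL	0.50	0.55	26.57	**	4
non-TNL_family40	non-TNL	0.78	0.77	6.29	*	0
non-TNL_family41	non-TNL	0.60	NA	NA	NA	0
non-TNL_family42	non-TNL	0.66	0.65	179.47	**	36
non-TNL_family43	non-TNL	0.42	0.52	13.77	**	0
non-TNL_family44	non-TNL	0.60	NA	NA	NA	0
non-TNL_family45	non-TNL	0.95	NA	NA	NA	0
non-TNL_family46	non-TNL	0.67	0.68	58.45	**	21
non-TNL_family47	non-TNL	0.31	0.34	160.78	**	5
non-TNL_family48	non-TNL	0.51	NA	NA	NA	0
non-TNL_family49	non-TNL	0.27	NA	NA	NA	0
non-TNL_family50	non-TNL	0.71	0.88	188.51	**	6
non-TNL_family51	non-TNL	0.47	0.44	69.96	**	15
non-TNL_family52	non-TNL	0.81	NA	NA	NA	0
non-TNL_family53	non-TNL	0.54	NA	NA	NA	0
non-TNL_family54	non-TNL	0.65	0.58	34.41	**	23
non-TNL_family55	non-TNL	1.70	2.23	113.38	**	1
non-TNL_family56	non-TNL	0.66	0.49	10.66	**	10
non-TNL_family57	non-TNL	0.51	0.32	0.00	ns	2
non-TNL_family58	non-TNL	0.55	0.42	15.31	**	1
non-TNL_family59	non-TNL	0.25	0.34	18.49	**	1
non-TNL_family60	non-TNL	NA	NA	NA	NA	0
non-TNL_family61	non-TNL	0.84	NA	NA	NA	0
non-TNL_family62	non-TNL	0.67	NA	NA	NA	0
non-TNL_family63	non-TNL	0.17	NA	NA	NA	0
non-TNL_family64	non-TNL	0.71	0.73	159.69	**	16
non-TNL_family65	non-TNL	0.45	0.50	8.95	*	25
non-TNL_family66	non-TNL	0.92	0.88	36.06	**	0
non-TNL_family67	non-TNL	0.44	0.15	0.00	ns	0
non-TNL_family68	non-TNL	0.82	NA	NA	NA	0
non-TNL_family69	non-TNL	0.55	0.32	8.34	*	1
non-TNL_family70	non-TNL	1.16	0.47	57.04	**	2
non-TNL_family71	non-TNL	0.70	NA	NA	NA	0
non-TNL_family72	non-TNL	0.93	1.16	7.52	*	0
non-TNL_family73	non-TNL	0.99	NA	NA	NA	0
non-TNL_family74	non-TNL	0.57	0.57	62.86	**	4
non-TNL_family75	non-TNL	0.63	0.80	4.68	ns	0
non-TNL_family76	non-TNL	0.58	0.57	9.64	**	6
non-TNL_family77	non-TNL	0.59	0.66	21.23	**	0
non-TNL_family78	non-TNL	0.62	NA	NA	NA	0
non-TNL_family79	non-TNL	0.57	0.55	80.40	**	11
non-TNL_family80	non-TNL	0.67	0.67	297.98	**	7
non-TNL_family81	non-TNL	0.55	0.63	15.57	**	0
non-TNL_family82	non-TNL	2.48	NA	NA	NA	0
non-TNL_family83	non-TNL	0.87	NA	NA	NA	0
non-TNL_family84	non-TNL	1.25	NA	NA	NA	0
non-TNL_family85	non-TNL	0.70	0.78	48.80	**	23
non-TNL_family86	non-TNL	1.21	1.29	91.70	**	0
non-TNL_family87	non-TNL	0.99	0.91	397.48	**	6
non-TNL_family88	non-TNL	0.89	1.09	27.11	**	3
non-TNL_family89	non-TNL	0.36	0.43	0.69	ns	0
non-TNL_family90	non-TNL	0.33	NA	NA	NA	0
non-TNL_family91	non-TNL	0.36	0.36	7.96	*	0
non-TNL_family92	non-TNL	0.31	0.32	0.75	ns	1
non-TNL_family93	non-TNL	0.42	NA	NA	NA	0
non-TNL_family94	non-TNL	0.71	NA	NA	NA	0
non-TNL_family95	non-TNL	0.72	NA	NA	NA	0
non-TNL_family96	non-TNL	0.60	NA	NA	NA	0
non-TNL_family97	non-TNL	0.87	0.89	54.59	**	3
non-TNL_family98	non-TNL	0.41	0.36	56.24	**	0
non-TNL_family99	non-TNL	0.58	0.54	3.18	ns	0
non-TNL_family100	non-TNL	0.25	0.22	1.64	ns	21
non-TNL_family101	non-TNL	0.56	0.61	9.90	**	15
non-TNL_family102	non-TNL	0.90	NA	NA	NA	0
non-TNL_family103	non-TNL	0.77	NA	NA	NA	0
non-TNL_family104	non-TNL	0.61	0.68	61.66	**	6
non-TNL_family105	non-TNL	0.60	0.53	20.30	**	0
non-TNL_family106	non-TNL	0.26	NA	NA	NA	0
non-TNL_family107	non-TNL	0.70	0.68	22.56	**	18
non-TNL_family108	non-TNL	0.49	NA	NA	NA	0
non-TNL_family109	non-TNL	0.29	0.32	0.00	ns	0
non-TNL_family110	non-TNL	0.45	NA	NA	NA	0
non-TNL_family111	non-TNL	0.60	0.45	14.82	**	1
non-TNL_family112	non-TNL	0.40	0.44	0.00	ns	0
non-TNL_family113	non-TNL	0.55	0.76	12.69	**	0
non-TNL_family114	non-TNL	0.76	NA	NA	NA	0
non-TNL_family115	non-TNL	0.37	NA	NA	NA	0
non-TNL_family116	non-TNL	0.76	0.80	102.63	**	7
non-TNL_family117	non-TNL	0.69	0.47	9.51	**	2
non-TNL_family118	non-TNL	0.68	0.60	46.89	**	3
non-TNL_family119	non-TNL	NA	NA	NA	NA	0
non-TNL_family120	non-TNL	0.42	NA	NA	NA	0
non-TNL_family121	non-TNL	0.24	NA	NA	NA	0
non-TNL_family122	non-TNL	0.20	0.26	0.41	ns	0
non-TNL_family123	non-TNL	0.50	NA	NA	NA	0
non-TNL_family124	non-TNL	1.62	0.77	72.18	**	1
non-TNL_family125	non-TNL	0.73	0.84	9.74	**	1
non-TNL_family126	non-TNL	0.62	NA	NA	NA	0
non-TNL_family127	non-TNL	0.34	NA	NA	NA	0
non-TNL_family128	non-TNL	0.53	0.51	22.29	**	6
non-TNL_family129	non-TNL	0.63	NA	NA	NA	0
non-TNL_family130	non-TNL	0.71	NA	NA	NA	0
non-TNL_family131	non-TNL	0.70	NA	NA	NA	0
non-TNL_family132	non-TNL	NA	NA	NA	NA	0
non-TNL_family133	non-TNL	1.06	NA	NA	NA	0
non-TNL_family134	non-TNL	0.90	NA	NA	NA	0
non-TNL_family135	non-TNL	0.62	NA	NA	NA	0
non-TNL_family136	non-TNL	0.75	NA	NA	NA	0
non-TNL_family137	non-TNL	0.75	NA	NA	NA	0
non-TNL_family138	non-TNL	0.84	NA	NA	NA	0
non-TNL_family139	non-TNL	0.52	NA	NA	NA	0
non-TNL_family140	non-TNL	0.68	NA	NA	NA	0
non-TNL_family141	non-TNL	0.69	NA	NA	NA	0
non-TNL_family142	non-TNL	0.49	NA	NA	NA	0
non-TNL_family143	non-TNL	0.80	NA	NA	NA	0
non-TNL_family144	non-TNL	1.22	NA	NA	NA	0
non-TNL_family145	non-TNL	0.53	NA	NA	NA	0
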