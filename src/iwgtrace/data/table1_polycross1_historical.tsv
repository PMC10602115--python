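rodale_accession	accession_id	pi_number	origin_country	collection_site	elevation_m	status	cultivar_name	site_is_garden	molecular	hsw_1988	hsw_1989	ssr_1988	ssr_1989	yield_1988	yield_1989
867	PI273732	273732	Russia	Rostov	NA	cultivated	Rostovsky 31	0	1	0.41	0.46	43	46	NA	2.81
869	PI286118	286118	Denmark	botanical garden	NA	uncertain	NA	1	1	0.49	0.52	45	49	NA	3.15
873	PI314054	314054	Russia	Rostov	NA	uncertain	NA	0	1	0.42	0.52	42	50	NA	3.64
875	PI315353	315353	Russia	Voronezh region	NA	uncertain	NA	0	0	0.42	0.42	51	38	NA	2.92
877	PI315355	315355	Russia	Stavropol region	NA	wild	NA	0	0	0.50	0.48	39	51	NA	3.36
878	PI316122	316122	Former USSR	NA	NA	uncertain	NA	0	1	0.51	0.55	49	46	2.89	2.99
833	PI326209	326209	Former USSR	Atai region	NA	wild	NA	0	0	0.55	0.44	51	43	3.95	2.02
785	PI401201	401201	Iran	SE of Khorranabad	1600	wild	NA	0	0	0.46	0.55	45	52	NA	2.85
793	PI440004	440004	Russia	NA	NA	cultivated	Rostov 31	0	1	0.51	0.49	48	47	3.03	2.79
797	PI440008	440008	Russia	SE of Stavropol	400	wild	NA	0	0	0.42	0.50	44	47	NA	2.75
800	PI440011	440011	Russia	near Svetlograd	250	wild	NA	0	0	0.57	0.45	44	47	NA	2.80
898	PI440014	440014	Russia	SE of Svetlograd	NA	wild	NA	0	0	0.52	0.45	46	45	2.14	1.89
899	PI440015	440015	Russia	SE of Svetlograd	300	cultivated	Rostov 31	0	1	0.55	0.49	50	47	3.46	2.60
901	PI440017	440017	Russia	SE of Svetlograd	300	wild	NA	0	0	0.52	0.52	49	41	2.49	2.10
836	PI440028	440028	Russia	SE of Stavropol	500	unknown	NA	0	0	0.50	0.43	43	35	NA	1.25
837	PI440029	440029	Russia	E of Stavropol	600	wild	NA	0	0	0.53	0.40	43	31	NA	1.25
839	PI440031	440031	Russia	E of Stavropol	400	wild	NA	0	0	0.59	0.50	45	37	2.89	1.62
918	PI440038	440038	Kazakhstan	SE of Dzhambul	1080	wild	NA	0	0	0.57	0.40	51	36	3.67	1.98
846	PI440039	440039	Kazakhstan	SE of Dzhambul	900	wild	NA	0	0	0.64	0.56	45	31	2.51	1.21
31	RI-31	NA	NA	NA	NA	unknown	NA	0	0	0.53	0.51	51	48	2.02	2.54
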