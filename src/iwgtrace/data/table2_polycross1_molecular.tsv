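rodale_accession	accession_id	pi_number	origin_country	collection_site	elevation_m	status	cultivar_name	site_is_garden	hsw_1988	hsw_1989	ssr_1988	ssr_1989	yield_1989
863	PI210992	210992	Afghanistan	Herat Province	NA	wild	NA	0	0.62	0.46	38	37	1.15
868	PI273733	273733	Russia	Kursk Oblast	NA	uncertain	NA	0	0.37	0.43	42	49	2.01
822	PI297876	297876	Russia	NA	NA	uncertain	NA	0	0.50	0.42	40	22	0.75
827	PI314192	314192	Uzbekistan	E Tashkent	NA	wild	NA	0	0.55	0.43	39	35	1.36
830	PI315065	315065	Former Soviet Union	NA	NA	uncertain	NA	0	0.47	0.41	40	38	2.14
874	PI315067	315067	Former Soviet Union	NA	NA	uncertain	NA	0	0.42	0.34	41	42	3.01
876	PI315354	315354	Russia	Stavropol	NA	wild	NA	0	0.47	0.48	46	42	2.06
831	PI325190	325190	Russia	Stavropol	NA	wild	NA	0	0.47	0.29	38	19	0.71
882	PI345586	345586	Russia	Rostov Region	NA	cultivated	Rostovskii 31	0	0.43	0.42	47	53	2.52
887	PI401014	401014	Turkey	Zongulkad	60	wild	NA	0	0.50	0.36	42	40	1.35
755	PI401015	401015	Turkey	Sinop	30	wild	NA	0	0.39	0.24	41	10	0.20
794	PI440005	440005	Russia	Stavropol	NA	cultivated	Stavropol-10	0	0.40	0.42	38	43	2.56
798	PI440009	440009	Russia	E Stavropol	600	wild	NA	0	0.42	0.46	39	37	1.44
902	PI440018	440018	Russia	SE Svetlograd	300	wild	NA	0	0.44	0.44	46	41	2.28
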