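accession_id	pi_number	origin_country	collection_site	elevation_m	status	cultivar_name	site_is_garden
PI173630	173630	Turkey	Solhan	NA	wild	NA	0
PI486197	486197	Turkmenistan	NA	NA	wild	NA	0
PI502351	502351	Russia	Elista	120	cultivated	NA	0
PI502356	502356	Russia	Stvropol	500	cultivated	NA	0
PI547315	547315	Russia	Leningrad Oblast	NA	wild	NA	0
PI547318	547318	Russia	NA	NA	cultivated	NA	0
PI547319	547319	Russia	Leningrad Oblast	NA	wild	NA	0
PI547334	547334	Poland	NA	NA	wild	NA	0
PI574518	574518	USA	NA	NA	breeding_material	NA	0
PI578695	578695	USA	NA	NA	breeding_material	NA	0
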