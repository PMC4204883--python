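suborder	superfamily	family	species	locus	n_total_clones	n_identical	n_unique_numts	n_numts_with_stop_or_indel
Caelifera	Acridoidea	Acrididae	Acrida willemsei	COI	47	35	12	1
Caelifera	Acridoidea	Acrididae	Acrida willemsei	COII	43	25	18	0
Caelifera	Acridoidea	Acrididae	Acrida willemsei	ND5	43	33	10	1
Caelifera	Acridoidea	Lentulidae	Lentula callani	COI	43	28	15	2
Caelifera	Acridoidea	Lentulidae	Lentula callani	COII	42	27	15	7
Caelifera	Acridoidea	Lentulidae	Lentula callani	ND5	26	14	12	9
Caelifera	Acridoidea	Lithidiidae	Lithiopsis carinatus	COI	42	18	24	8
Caelifera	Acridoidea	Lithidiidae	Lithiopsis carinatus	COII	46	27	19	9
Caelifera	Acridoidea	Lithidiidae	Lithiopsis carinatus	ND5	24	8	16	9
Caelifera	Acridoidea	Pamphagidae	Prionotropis hystrix	COI	46	24	22	3
Caelifera	Acridoidea	Pamphagidae	Prionotropis hystrix	COII	40	19	20	16
Caelifera	Acridoidea	Pamphagidae	Prionotropis hystrix	ND5	42	31	11	4
Caelifera	Acridoidea	Pamphagodidae	Hemicharilaus monomorphus	COI	46	31	15	1
Caelifera	Acridoidea	Pamphagodidae	Hemicharilaus monomorphus	COII	16	13	3	0
Caelifera	Acridoidea	Pamphagodidae	Hemicharilaus monomorphus	ND5	30	3	27	27
Caelifera	Acridoidea	Pyrgacrididae	Pyrgacris descampsi	COI	23	21	2	2
Caelifera	Acridoidea	Pyrgacrididae	Pyrgacris descampsi	COII	54	40	14	3
Caelifera	Acridoidea	Pyrgacrididae	Pyrgacris descampsi	ND5	38	27	11	0
Caelifera	Acridoidea	Romaleidae	Xyleus modestus	COI	45	31	13	3
Caelifera	Acridoidea	Romaleidae	Xyleus modestus	COII	47	30	14	0
Caelifera	Acridoidea	Romaleidae	Xyleus modestus	ND5	45	27	18	2
Caelifera	Acridoidea	Tristiridae	Tristira magellanica	COI	43	27	16	2
Caelifera	Acridoidea	Tristiridae	Tristira magellanica	COII	43	22	21	5
Caelifera	Acridoidea	Tristiridae	Tristira magellanica	ND5	36	17	18	7
Caelifera	Eumastacoidea	Chorotypidae	Chorotypus fenestratus	COI	36	27	9	1
Caelifera	Eumastacoidea	Chorotypidae	Chorotypus fenestratus	COII	16	15	1	0
Caelifera	Eumastacoidea	Chorotypidae	Chorotypus fenestratus	ND5	45	41	4	3
Caelifera	Eumastacoidea	Eumastacidae	Paramastax nigra	COI	40	16	23	5
Caelifera	Eumastacoidea	Eumastacidae	Paramastax nigra	COII	9	2	7	7
Caelifera	Eumastacoidea	Eumastacidae	Paramastax nigra	ND5	45	27	18	3
Caelifera	Pneumoroidea	Pneumoridae	Physemacris variolosa	COI	44	28	16	3
Caelifera	Pneumoroidea	Pneumoridae	Physemacris variolosa	ND5	24	11	13	10
Caelifera	Proscopioidea	Proscopiidae	Proscopia sp.	COI	44	0	8	0
Caelifera	Proscopioidea	Proscopiidae	Proscopia sp.	COII	27	0	8	8
Caelifera	Proscopioidea	Proscopiidae	Proscopia sp.	ND5	42	31	11	7
Caelifera	Proscopioidea	Thericleidae	Pseudothericles compressifrons	COI	32	20	12	3
Caelifera	Proscopioidea	Thericleidae	Pseudothericles compressifrons	COII	24	13	11	1
Caelifera	Proscopioidea	Thericleidae	Pseudothericles compressifrons	ND5	41	30	10	0
Caelifera	Pyrgomorphoidea	Pyrgomorphidae	Atractomorpha sinensis	COI	22	18	4	0
Caelifera	Pyrgomorphoidea	Pyrgomorphidae	Atractomorpha sinensis	COII	42	27	15	6
Caelifera	Tetrigoidea	Tetrigidae	Trachytettix horridus	COI	61	2	32	9
Caelifera	Tetrigoidea	Tetrigidae	Trachytettix horridus	ND5	17	12	5	4
Caelifera	Tridactyloidea	Cylindrachetidae	Cylindraustralia sp.	COI	45	26	11	0
Caelifera	Tridactyloidea	Cylindrachetidae	Cylindraustralia sp.	COII	41	24	17	3
Caelifera	Tridactyloidea	Cylindrachetidae	Cylindraustralia sp.	ND5	36	30	6	6
Caelifera	Tridactyloidea	Ripipterygidae	Mirrhipipteryx andensis	COI	45	33	10	1
Caelifera	Tridactyloidea	Ripipterygidae	Mirrhipipteryx andensis	COII	5	2	3	0
Caelifera	Tridactyloidea	Ripipterygidae	Mirrhipipteryx andensis	ND5	46	39	7	0
Caelifera	Tridactyloidea	Tridactylidae	Ellipes minuta	COI	45	38	7	2
Caelifera	Tridactyloidea	Tridactylidae	Ellipes minuta	COII	37	29	8	2
Caelifera	Tridactyloidea	Tridactylidae	Ellipes minuta	ND5	34	1	16	3
Caelifera	Trigonopterygoidea	Trigonopterygidae	Trigonopteryx hopei	COI	37	22	15	5
Caelifera	Trigonopterygoidea	Trigonopterygidae	Trigonopteryx hopei	COII	6	2	4	3
Caelifera	Trigonopterygoidea	Trigonopterygidae	Trigonopteryx hopei	ND5	32	16	16	9
Ensifera	Gryllacridoidea	Gryllacrididae	Camptonotus carolinensis	COI	45	24	19	4
Ensifera	Gryllacridoidea	Gryllacrididae	Camptonotus carolinensis	COII	46	30	16	4
Ensifera	Gryllacridoidea	Gryllacrididae	Camptonotus carolinensis	ND5	43	27	15	4
Ensifera	Grylloidea	Gryllotalpidae	Gryllotalpa pluvialis	COI	33	28	3	0
Ensifera	Grylloidea	Myrmecophilidae	Myrmecophila manni	COI	92	57	26	1
Ensifera	Grylloidea	Myrmecophilidae	Myrmecophila manni	COII	41	31	9	4
Ensifera	Hagloidea	Prophalangopsidae	Cyphoderris monstrosa	COI	37	23	14	1
Ensifera	Hagloidea	Prophalangopsidae	Cyphoderris monstrosa	COII	42	19	22	12
Ensifera	Hagloidea	Prophalangopsidae	Cyphoderris monstrosa	ND5	42	21	21	9
Ensifera	Schizodactyloidea	Schizodactylidae	Comicus campestris	COI	46	38	8	0
Ensifera	Schizodactyloidea	Schizodactylidae	Comicus campestris	COII	9	8	1	0
Ensifera	Schizodactyloidea	Schizodactylidae	Comicus campestris	ND5	44	33	11	0
Ensifera	Stenopelmatoidea	Anostostomatidae	Henicus brevimucronatus	COI	18	14	4	1
Ensifera	Stenopelmatoidea	Anostostomatidae	Henicus brevimucronatus	COII	13	12	1	0
Ensifera	Stenopelmatoidea	Rhaphidophoridae	Troglophilus neglectus	COI	44	25	19	6
Ensifera	Stenopelmatoidea	Rhaphidophoridae	Troglophilus neglectus	COII	46	21	25	3
Ensifera	Stenopelmatoidea	Rhaphidophoridae	Troglophilus neglectus	ND5	43	22	21	10
Ensifera	Stenopelmatoidea	Stenopelmatidae	Stenopelmatus fuscus	COI	44	22	20	5
Ensifera	Stenopelmatoidea	Stenopelmatidae	Stenopelmatus fuscus	COII	46	38	8	0
Ensifera	Stenopelmatoidea	Stenopelmatidae	Stenopelmatus fuscus	ND5	27	21	6	1
Ensifera	Tettigonioidea	Tettigoniidae	Anabrus simplex	COI	68	27	41	12
Ensifera	Tettigonioidea	Tettigoniidae	Anabrus simplex	COII	36	17	9	0
Ensifera	Tettigonioidea	Tettigoniidae	Anabrus simplex	ND5	29	16	13	0
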