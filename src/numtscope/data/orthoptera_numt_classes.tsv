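family	species	locus	n_paleonumt	n_neonumt
Acrididae	Acrida willemsei	COI	5	7
Acrididae	Acrida willemsei	COII	2	16
Acrididae	Acrida willemsei	ND5	1	9
Lentulidae	Lentula callani	COI	3	12
Lentulidae	Lentula callani	COII	7	8
Lentulidae	Lentula callani	ND5	0	12
Lithidiidae	Lithiopsis carinatus	COI	18	6
Lithidiidae	Lithiopsis carinatus	COII	12	7
Lithidiidae	Lithiopsis carinatus	ND5	8	8
Pamphagidae	Prionotropis hystrix	COI	10	12
Pamphagidae	Prionotropis hystrix	COII	16	4
Pamphagidae	Prionotropis hystrix	ND5	5	6
Pamphagodidae	Hemicharilaus monomorphus	COI	2	13
Pamphagodidae	Hemicharilaus monomorphus	COII	1	2
Pamphagodidae	Hemicharilaus monomorphus	ND5	25	2
Pyrgacrididae	Pyrgacris descampsi	COI	0	2
Pyrgacrididae	Pyrgacris descampsi	COII	5	9
Pyrgacrididae	Pyrgacris descampsi	ND5	1	10
Romaleidae	Xyleus modestus	COI	2	11
Romaleidae	Xyleus modestus	COII	1	13
Romaleidae	Xyleus modestus	ND5	1	17
Tristiridae	Tristira magellanica	COI	6	10
Tristiridae	Tristira magellanica	COII	6	15
Tristiridae	Tristira magellanica	ND5	11	7
Chorotypidae	Chorotypus fenestratus	COI	1	8
Chorotypidae	Chorotypus fenestratus	COII	0	1
Chorotypidae	Chorotypus fenestratus	ND5	0	4
Eumastacidae	Paramastax nigra	COI	14	9
Eumastacidae	Paramastax nigra	COII	0	7
Eumastacidae	Paramastax nigra	ND5	6	12
Thericleidae	Pseudothericles compressifrons	COI	5	7
Thericleidae	Pseudothericles compressifrons	COII	2	9
Thericleidae	Pseudothericles compressifrons	ND5	1	9
Pneumoridae	Physemacris variolosa	COI	5	11
Pneumoridae	Physemacris variolosa	ND5	8	5
Proscopiidae	Proscopia sp.	COI	8	0
Proscopiidae	Proscopia sp.	COII	0	8
Proscopiidae	Proscopia sp.	ND5	1	10
Pyrgomorphidae	Atractomorpha sinensis	COI	0	4
Pyrgomorphidae	Atractomorpha sinensis	COII	1	14
Tetrigidae	Trachytettix horridus	COI	13	19
Tetrigidae	Trachytettix horridus	ND5	0	5
Cylindrachetidae	Cylindraustralia sp.	COI	4	7
Cylindrachetidae	Cylindraustralia sp.	COII	1	16
Cylindrachetidae	Cylindraustralia sp.	ND5	2	4
Ripipterygidae	Mirrhipipteryx andensis	COI	6	4
Ripipterygidae	Mirrhipipteryx andensis	COII	1	2
Ripipterygidae	Mirrhipipteryx andensis	ND5	0	7
Tridactylidae	Ellipes minuta	COI	1	6
Tridactylidae	Ellipes minuta	COII	4	4
Tridactylidae	Ellipes minuta	ND5	15	1
Trigonopterygidae	Trigonopteryx hopei	COI	9	6
Trigonopterygidae	Trigonopteryx hopei	COII	3	1
Trigonopterygidae	Trigonopteryx hopei	ND5	3	13
Gryllacrididae	Camptonotus carolinensis	COI	2	17
Gryllacrididae	Camptonotus carolinensis	COII	2	14
Gryllacrididae	Camptonotus carolinensis	ND5	3	12
Gryllotalpidae	Gryllotalpa pluvialis	COI	0	3
Myrmecophilidae	Myrmecophila manni	COI	1	25
Myrmecophilidae	Myrmecophila manni	COII	4	5
Prophalangopsidae	Cyphoderris monstrosa	COI	4	10
Prophalangopsidae	Cyphoderris monstrosa	COII	14	8
Prophalangopsidae	Cyphoderris monstrosa	ND5	3	18
Schizodactylidae	Comicus campestris	COI	1	7
Schizodactylidae	Comicus campestris	COII	0	1
Schizodactylidae	Comicus campestris	ND5	1	10
Anostostomatidae	Henicus brevimucronatus	COI	0	4
Anostostomatidae	Henicus brevimucronatus	COII	0	1
Rhaphidophoridae	Troglophilus neglectus	COI	13	6
Rhaphidophoridae	Troglophilus neglectus	COII	10	15
Rhaphidophoridae	Troglophilus neglectus	ND5	15	6
Stenopelmatidae	Stenopelmatus fuscus	COI	10	10
Stenopelmatidae	Stenopelmatus fuscus	COII	1	7
Stenopelmatidae	Stenopelmatus fuscus	ND5	0	6
Tettigoniidae	Anabrus simplex	COI	27	14
Tettigoniidae	Anabrus simplex	COII	2	7
Tettigoniidae	Anabrus simplex	ND5	1	12
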