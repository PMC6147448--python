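sample_id	stage_code	hvr1	coding	haplogroup
Tg38	P	16183C-16189C-16223T-16290T-16319A-16362C	663G	A
Tg77	P	16075C-16223T-16242T-16290T-16319A	663G	A8
Tg122	S	16223T-16242T-16278T-16290T-16319A	663G	A8
Tg21	Bidj	16129A-16223T-16242T-16278T-16290T-16319A	663G	A8
Tg106	P	16129A-16223T-16242T-16278T-16290T-16319A	663G	A8
Tg120	P	16129A-16223T-16242T-16278T-16290T-16319A	663G	A8
Tg102	S	16193T-16223T-16242T-16278T-16290T-16319A	663G	A8
Tg1	P	16223T-16242T-16278T-16290T-16311C-16319A	663G	A8
Tg60	P	16223T-16242T-16278T-16290T-16311C-16319A	663G	A8
Tg37	S	16093C-16129A-16223T-16298C-16327T	10398G,10400T,13263G	C
Tg85	T	16093C-16129A-16223T-16298C-16327T	10398G,10400T,13263G	C
Tg110	S	16093C-16129A-16223T-16298C-16327T	10398G,10400T,13263G	C
Tg3	S	16223T-16298C-16327T-16344T-16357C	10398G,10400T,13263G	C4a2a
Tg2	S	16037G-16171G-16223T-16298C-16327T-16344T-16357C	10398G,10400T,13263G	C4a2a1
Tg46	P	16171G-16223T-16298C-16327T-16344T-16357C	10398G,10400T,13263G	C4a2a1
Tg76	P	16093C-16223T-16288C-16298C-16327T	10398G,10400T,13263G	C5
Tg24	Bain	16223T-16362C	10398G,10400T,5178A	D
Tg34	S	16223T-16362C	10398G,10400T,5178A	D
Tg91	S	16223T-16362C	10398G,10400T,5178A	D
Tg100	S	16223T-16362C	10398G,10400T,5178A	D
Tg123	P	16223T-16362C	10398G,10400T,5178A	D
Tg112	S	16223T-16320T-16362C	10398G,10400T,5178A	D
Tg121	S	16223T-16320T-16362C	10398G,10400T,5178A	D
Tg29	P	16189C-16232A-16249C-16304C-16311C	6392C	F1b
Tg33	P	16172C-16179T-16183C-16189C-16232A-16249C-16304C-16311C	6392C	F1b1b
Tg42	P	16093C-16223T-16227G-16278T-16362C	10398G,10400T,4833G	G2a
Tg56	P	16093C-16223T-16227G-16278T-16362C	10398G,10400T,4833G	G2a
Tg71	P	16093C-16223T-16227G-16278T-16362C	10398G,10400T,4833G	G2a
Tg61	P	16256T	14766C,7028C	H
Tg108	P	16304C	14766C,7028C	H
Tg18	P	16311C	14766C,7028C	H
Tg23	P	16311C	14766C,7028C	H
Tg10	T	16172C-16311C	14766C,7028T	HV6
Tg69	P	16172C-16311C	14766C,7028T	HV6
Tg84	T	16172C-16311C	14766C,7028T	HV6
Tg111	S	16158T-16311C	14766C,7028T	HV*
Tg74	P	16129A-16223T-16304C-16391A	10034C	I
Tg80	P	16129A-16223T-16304C-16391A	10034C	I
Tg89	T	16129A-16223T-16304C-16391A	10034C	I
Tg12	P	16224C-16311C	12308G	K
Tg59	P	16093C-16224C-16311C-16319A	12308G	K1b1a
Tg66	Bidj	16093C-16224C-16311C-16319A	12308G	K1b1a
Tg54	P	16224C-16311C-16320T	12308G	K1c2
Tg11	P	16126C-16163G-16186T-16189C-16294T	4917G	T1
Tg19	Bidj	16126C-16163G-16186T-16189C-16294T	4917G	T1
Tg62	P	16126C-16163G-16186T-16189C-16294T	4917G	T1
Tg86	T	16126C-16163G-16186T-16189C-16294T	4917G	T1
Tg88	T	16126C-16163G-16186T-16189C-16294T	4917G	T1
Tg94	P	16126C-16163G-16186T-16189C-16294T	4917G	T1
Tg96	S	16126C-16163G-16186T-16189C-16294T	4917G	T1
Tg109	S	16126C-16163G-16186T-16189C-16294T	4917G	T1
Tg115	S	16126C-16163G-16186T-16189C-16294T	4917G	T1
Tg116	P	16126C-16163G-16186T-16189C-16294T	4917G	T1
Tg101	S	16126C-16163G-16186T-16189C-16269G-16294T-16362C	4917G	T1
Tg14	P	16126C-16189C-16292T-16294T-16296T	4917G	T2f7
Tg26	P	16126C-16189C-16292T-16294T-16296T	4917G	T2f7
Tg49	P	16126C-16189C-16292T-16294T-16296T	4917G	T2f7
Tg87	T	16126C-16189C-16292T-16294T	4917G	T
Tg113	S	16126C-16189C-16292T-16294T	4917G	T
Tg39	P	16051G-16129C-16183C-(16193insC)-16362C	12308G	U2e
Tg92	S	16051G-16129C-16183C-(16193insC)-16362C	12308G	U2e
Tg93	S	16051G-16129C-16183C-(16193insC)-16362C	12308G	U2e
Tg70	P	16051G-16092C-16129C-16189C-16260T-16362C	12308G	U2e
Tg58	P	16051G-16129C-16189C-16246G-16362C-16391A	12308G	U2e
Tg75	S	16051G-16129C-16189C-16246G-16362C-16391A	12308G	U2e
Tg97	P	16356C	12308G	U4
Tg57	P	16134T-16356C	12308G	U4
Tg6	T	16356C-16362C	12308G	U4a3
Tg9	T	16356C-16362C	12308G	U4a3
Tg17	P	16356C-16362C	12308G	U4a3
Tg72	S	16356C-16362C	12308G	U4a3
Tg83	P	16356C-16362C	12308G	U4a3
Tg117	S	16356C-16362C	12308G	U4a3
Tg67	S	16192T-16256T-16270T-16399G	12308G	U5a1
Tg30	Bidj	16192T-16239T-16256T-16270T-16399G	12308G	U5a1h
Tg99	P	16256T-16270T-16309G	12308G	U5a
Tg41	P	rCRS	14766T,7028T,12308G	U*
Tg73	P	rCRS	14766T,7028T,12308G	U*
Tg119	S	rCRS	14766T,7028T,12308G	U*
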