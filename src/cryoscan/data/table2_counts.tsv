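strain	pair	accession	group	LadA	AlmA	AlkB	AlkB_like	p450_bacterial	p450_eukaryotic
Aeromonas salmonicida A449	A	CP000644	psychrophile	0	0	0	0	0	0
Aliivibrio salmonicida LFI1238	B	FM178379	psychrophile	0	0	0	0	0	0
Colwellia psychrerythraea 34H	C	CP000083	psychrophile	0	0	0	0	0	0
Desulfotalea psychrophila LSv54	D	CR522870	psychrophile	0	0	0	0	0	0
Flavobacterium psychrophilum JIP02 86	E	AM398681	psychrophile	0	0	0	0	0	0
Glaciecola psychrophila 170	F	CP003837	psychrophile	0	5	0	1	1	0
Methanococcoides burtonii DSM 6242	G	CP000300	psychrophile	0	0	0	0	0	0
Octadecabacter antarcticus 307	H	CP003740	psychrophile	1	0	2	2	1	1
Octadecabacter arcticus 238	I	CP003742	psychrophile	1	0	2	1	1	1
Photobacter profundum SS9	J	CR354532	psychrophile	0	0	0	0	0	1
Pseudoalteromonas haloplanktis TAC125	K	CR954246	psychrophile	0	0	0	0	0	0
Psychrobacter arcticum 273-4	L	CP000082	psychrophile	0	0	0	0	0	0
Psychrobacter cryohalolentis K5	M	CP000323	psychrophile	0	1	0	0	0	0
Psychroflexus torquis ATCC700755	N	CP003879	psychrophile	0	0	0	0	0	1
Psychromonas CNPT3	O	CP004404	psychrophile	0	0	0	0	0	0
Psychromonas ingrahamii 37	P	CP000510	psychrophile	0	0	0	0	0	0
Shewanella halifaxensis HAW EB4	Q	CP000931	psychrophile	0	0	0	0	0	0
Shewanella sediminis HAW-EB3	R	CP000821	psychrophile	0	0	0	0	0	0
Shewanella violacea DSS12	S	AP011177	psychrophile	0	0	0	0	0	0
Terroglobus saanensis SP1PR4	T	CP002467	psychrophile	1	0	0	0	2	1
Aeromonas veronii B565	A	CP002607	mesophile	0	0	0	0	0	0
Vibrio fischeri ES114	B	CP000020	mesophile	0	0	0	0	0	0
Alteromonas macleodii Deep ecotype	C	CP001103	mesophile	0	1	0	0	0	0
Desulfocapsa sulfexigens DSM 10523	D	CP003985	mesophile	0	0	0	0	0	0
Flavobacterium indicum GPTSA100 9	E	HE774682	mesophile	0	0	0	0	0	0
Glaciecola agarilytica 4H37Ye5	F	CP002526	mesophile	0	1	0	0	3	0
Methanosarcina mazei Tuc01	G	CP004144	mesophile	0	0	0	0	0	0
Rhodobacter sphaeroides ATCC 17025	H	CP000661	mesophile	0	0	1	0	1	0
Ketogulonicigenium vulgare Y25	I	CP002224	mesophile	0	1	0	0	0	1
Vibrio vulnificus YJ016	J	AP005352	mesophile	0	0	0	0	0	0
Pseudoalteromonas atlantica T6c	K	CP000388	mesophile	0	0	0	0	1	0
Acinetobacter baumannii ACICU	L	CP000863	mesophile	2	4	1	1	0	0
Acinetobacter baumannii AYE	M	CU459141	mesophile	2	6	1	1	0	0
Flavobacteriales bacterium HTCC2170	N	CP002157	mesophile	0	0	1	0	0	0
Marinobacter aquaeolei VT8	O	CP000514	mesophile	0	3	3	1	2	0
Alteromonas macleodii English Channel ecotype	P	CP003844	mesophile	0	1	0	0	0	0
Shewanella MR-7	Q	CP000444	mesophile	0	0	0	0	0	0
Shewanella denitrificans OS217	R	CP000302	mesophile	0	1	0	0	0	0
Shewanella putrefaciens 200	S	CP002457	mesophile	0	0	0	0	0	0
Terriglobus roseus DSM18391	T	CP003379	mesophile	0	0	0	0	0	1
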