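role	peptide	preceding	following	site_p1	span_start	abundance_active	abundance_control
semi	SPLGSDLGPQMLRELQETNAALQDVRELLR	Q	Q	23		500000.0	
semi	GSDLGPQMLRELQETNAALQDVRELLR	L	Q	26		500000.0	
semi	LGPQMLRELQETNAALQDVRELLR	D	Q	29		500000.0	
semi	LRELQETNAALQDVRELLR	M	Q	34		500000.0	
semi	NTVMECDACGMQQ	K	S	76		500000.0	
semi	QQVREITFLKNTVMECDACGMQQ	R	S	76		500000.0	
semi	VRTGLPSVRPLLHCAPGFCFPGVACIQTESGAR	S	C	77		2303500.0	10000.0
semi	EITFLKNTVMECDACGMQQS	R	V	77		1020100.0	10000.0
semi	QQVREITFLKNTVMECDACGMQQS	R	V	77		500000.0	
semi	LPSVRPLLHCAPGFCFPGVACIQTESGAR	G	C	81		500000.0	
semi	TGLPSVRPLLHCAPGFCFPGVACIQT	R	E	105		500000.0	
semi	INECETGQHNCVPNSVCINTR	D	G	180		500000.0	
semi	ANKQVCTDINECETGQHNCV	K	P	192		500000.0	
semi	FCPDGSPSECHEHADCVLERD	R	G	248		500000.0	
semi	QDDFDADKVVDKIDVCPENAEVTLTDFR	C	A	504		500000.0	
semi	FRAFQTVVLDPEGDAQIDPNWVVLNQGR	D	E	530		500000.0	
semi	AFQTVVLDPEGDAQIDPNWVVLNQGREIVQTMNSDPGLAVGYTA	R	F	576		500000.0	
semi	QMEQTYWQANPFRA	K	V	629		500000.0	
semi	QMEQTYWQANPFRAVAEPGIQLKA	K	V	639		500000.0	
semi	LRQAFEGKPIPNPLLGLDSTR	Q	T	753		500000.0	
spanning	EITFLKNTVMECDACGMQQSVR	R	T		58		500000.0
spanning	QQVREITFLKNTVMECDACGMQQSVR	R	T		54		500000.0
spanning	FCPDGSPSECHEHADCVLERDGSR	R	S		228		500000.0
spanning	DGSRSCVCAVGWAGNGILCGR	R	D		248		500000.0
spanning	AVKSSTGPGEQLRNALWHTGDTESQVR	K	L		639	10000.0	1508200.0
background	NFQSFNSYK	R	G			793.2806	10000.0
background	WLVYILIGR	R	G			843.5623	10000.0
background	GVEAFVVWK	R	G			897.031	10000.0
background	QMFACYDYR	R	G			953.8888	10000.0
background	EIMQEWWNK	R	G			1014.3506	10000.0
background	YICQAVTAR	R	G			1078.6446	10000.0
background	TYYMASHQK	R	G			1147.0139	10000.0
background	HDEITEDYR	R	G			1219.7168	10000.0
background	LSICFDQDK	R	G			1297.0279	10000.0
background	GEQVQDYAR	R	G			1379.2393	10000.0
background	EATHCSNGK	R	G			1466.6616	10000.0
background	EELGTIQCR	R	G			1559.6252	10000.0
background	CDEIVSFCK	R	G			1658.4812	10000.0
background	QGNWISAWR	R	G			1763.6031	10000.0
background	GNFCSDICK	R	G			1875.3881	10000.0
background	YSDWVLTDR	R	G			1994.2586	10000.0
background	WTEVQCHQK	R	G			2120.6636	10000.0
background	YDFFGALIR	R	G			2255.0807	10000.0
background	HSSCHIDMK	R	G			2398.0177	10000.0
background	NVLMMNGQR	R	G			2550.0148	10000.0
background	GACHHYVDK	R	G			2711.6461	10000.0
background	SNNAGMINR	R	G			2883.5223	10000.0
background	QFNTVDCAK	R	G			3066.2928	10000.0
background	CIMSFTTCR	R	G			3260.6481	10000.0
background	VCNEWSQYK	R	G			3467.3225	10000.0
background	NTESNNQDR	R	G			3687.0969	10000.0
background	DLWMEDIFK	R	G			3920.8015	10000.0
background	MYYMIISER	R	G			4169.3194	10000.0
background	SFHHAWLGK	R	G			4433.5895	10000.0
background	LFHYTDQQR	R	G			4714.6101	10000.0
background	DYAYHLYDK	R	G			5013.4432	10000.0
background	AMNFGWHDR	R	G			5331.2175	10000.0
background	ATDLYMMSK	R	G			5669.1339	10000.0
background	QWHHMWFTR	R	G			6028.4689	10000.0
background	HFNYFLHQK	R	G			6410.5801	10000.0
background	HAGDTGCGR	R	G			6816.9112	10000.0
background	DIVIHDQGK	R	G			7248.9975	10000.0
background	LQVYCHIHR	R	G			7708.4712	10000.0
background	SFWQCHILK	R	G			8197.0685	10000.0
background	DLMFIQWQR	R	G			8716.6352	10000.0
background	SYAMGVCHK	R	G			9269.1344	10000.0
background	FGDTNGYMR	R	G			9856.6535	10000.0
background	NWVMFTALK	R	G			10481.4122	10000.0
background	MTWYCHLLR	R	G			11145.7708	10000.0
background	LVGGLQAWK	R	G			11852.2394	10000.0
background	DDYDTALHR	R	G			12603.4872	10000.0
background	YFSTDIFDK	R	G			13402.3524	10000.0
background	YVAVIADNR	R	G			14251.8533	10000.0
background	ICTGVFASK	R	G			15155.1992	10000.0
background	EFTGGYDYR	R	G			16115.8033	10000.0
background	VYLLFITMK	R	G			17137.2948	10000.0
background	NAWDMCWHR	R	G			18223.5329	10000.0
background	WDSFCHAHK	R	G			19378.6217	10000.0
background	DFVWFGFGR	R	G			20606.9251	10000.0
background	ETDDGLIAK	R	G			21913.0839	10000.0
background	VHVGWWQFR	R	G			23302.0329	10000.0
background	VILISIYHK	R	G			24779.0196	10000.0
background	HASLSDCNR	R	G			26349.6243	10000.0
background	ETSNAFVLK	R	G			28019.781	10000.0
background	QTFYEEGIR	R	G			29795.7996	10000.0
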