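role	peptide	preceding	following	site_p1	span_start	abundance_active	abundance_control
semi	SVRTGLPSVRPLLHCAPGFCFPGVACIQTESGAR	Q	C	76		500000.0	
semi	VRTGLPSVRPLLHCAPGFCFPGVACIQTESGAR	S	C	77		1426100.0000000002	10000.0
semi	NTVMECDACGMQQS	K	V	77		500000.0	
semi	EITFLKNTVMECDACGMQQS	R	V	77		500000.0	
semi	VRPLLHCAPGFCFPGVACIQTESGAR	S	C	84		500000.0	
semi	CIQTESGAR	A	C	101		500000.0	
semi	TGLPSVRPLLHCAPGFCFPGVACIQTE	R	S	106		500000.0	
semi	QVCTDINECETGQHNCVPN	K	S	194		500000.0	
semi	PDGSPSECHEHADCVLER	C	D	229		500000.0	
semi	SCVCAVGWAGNGILCGRD	R	T	269		500000.0	
semi	NCVTVPNSGQEDVDRDGIGDACDPDADGDGVPNEKDNCPLVR	D	N	290		500000.0	
semi	VTVPNSGQEDVDRDGIGDACDPDADGDGVPNEKDNCPLVR	C	N	292		500000.0	
semi	VDRDGIGDACDPDADGDGVPNEKDNCPLVR	D	N	302		500000.0	
semi	KDNCVTVPNSGQEDVDRDGIGD	R	A	310		500000.0	
semi	CDPDADGDGVPNEKDNCPLVR	A	N	311		500000.0	
semi	DADGDGVPNEKDNCPLVR	P	N	314		500000.0	
semi	DGDGVPNEKDNCPLVR	A	N	316		500000.0	
semi	VPNEKDNCPLVR	G	N	320		500000.0	
semi	DNCVTVPNSGQEDVDRDGIGDACDPDADGDGVPN	K	E	323		500000.0	
semi	PDQADVDHDFVGDACDSDQDQDGDGHQDSR	N	D	415		500000.0	
semi	GVGDVCQDDFDADKVVDKIDVCPENAEVTLTDFR	D	A	498		500000.0	
semi	LVPNPGQEDADRDGVGD	R	V	502		500000.0	
semi	IDVCPENAEVTLT	K	D	529		500000.0	
semi	RAFQTVVLDPEGDAQIDPNWVVLNQGR	F	E	531		500000.0	
semi	TVVLDPEGDAQIDPNWVVLNQGR	Q	E	535		500000.0	
semi	VVLDPEGDAQIDPNWVVLNQGR	T	E	536		500000.0	
semi	WVVLNQGR	N	E	550		500000.0	
semi	AFQTVVLDPEGDAQIDPNWVVLNQ	R	G	556		500000.0	
semi	EIVQTMNSDPGLAVGYTAF	R	N	577		500000.0	
semi	GPELVADSNVVLDTTMRGGR	E	L	701		500000.0	
semi	FYEGPELVADSNVVLDTT	R	M	716		500000.0	
semi	FYEGPELVADSNVVLDTTM	R	R	717		500000.0	
semi	VRFYEGPELVADSNVVLDTTM	R	R	717		500000.0	
semi	LGVFCFS	R	Q	728		500000.0	
semi	LRQAFEGKPIPNPLLGLDSTR	Q	T	753		500000.0	
spanning	EITFLKNTVMECDACGMQQSVR	R	T		58	10000.0	713000.0
spanning	ANKQVCTDINECETGQHNCVPNSVCINTR	K	G		173	10000.0	7380000.0
spanning	AQRFCPDGSPSECHEHADCVLERDGSR	R	S		225		500000.0
spanning	DNCVTVPNSGQEDVDR	K	D		290		500000.0
spanning	DGIGDACDPDADGDGVPNEKDNCPLVR	R	N		306		500000.0
spanning	DGIGDACDPDADGDGVPNEKDNCPLVRNPDQR	R	N		306		500000.0
spanning	DGVGDVCQDDFDADKVVDK	R	I		498		500000.0
background	NFQSFNSYK	R	G			3428.5096	10000.0
background	WLVYILIGR	R	G			3567.6746	10000.0
background	GVEAFVVWK	R	G			3712.4884	10000.0
background	QMFACYDYR	R	G			3863.1802	10000.0
background	EIMQEWWNK	R	G			4019.9886	10000.0
background	YICQAVTAR	R	G			4183.1621	10000.0
background	TYYMASHQK	R	G			4352.9588	10000.0
background	HDEITEDYR	R	G			4529.6476	10000.0
background	LSICFDQDK	R	G			4713.5083	10000.0
background	GEQVQDYAR	R	G			4904.832	10000.0
background	EATHCSNGK	R	G			5103.9217	10000.0
background	EELGTIQCR	R	G			5311.0925	10000.0
background	CDEIVSFCK	R	G			5526.6725	10000.0
background	QGNWISAWR	R	G			5751.003	10000.0
background	GNFCSDICK	R	G			5984.4391	10000.0
background	YSDWVLTDR	R	G			6227.3506	10000.0
background	WTEVQCHQK	R	G			6480.122	10000.0
background	YDFFGALIR	R	G			6743.1534	10000.0
background	HSSCHIDMK	R	G			7016.8615	10000.0
background	NVLMMNGQR	R	G			7301.6795	10000.0
background	GACHHYVDK	R	G			7598.0585	10000.0
background	SNNAGMINR	R	G			7906.4676	10000.0
background	QFNTVDCAK	R	G			8227.3952	10000.0
background	CIMSFTTCR	R	G			8561.3494	10000.0
background	VCNEWSQYK	R	G			8908.8589	10000.0
background	NTESNNQDR	R	G			9270.4741	10000.0
background	DLWMEDIFK	R	G			9646.7674	10000.0
background	MYYMIISER	R	G			10038.3347	10000.0
background	SFHHAWLGK	R	G			10445.7958	10000.0
background	LFHYTDQQR	R	G			10869.7961	10000.0
background	DYAYHLYDK	R	G			11311.0067	10000.0
background	AMNFGWHDR	R	G			11770.1263	10000.0
background	ATDLYMMSK	R	G			12247.8817	10000.0
background	QWHHMWFTR	R	G			12745.0296	10000.0
background	HFNYFLHQK	R	G			13262.3569	10000.0
background	HAGDTGCGR	R	G			13800.6828	10000.0
background	DIVIHDQGK	R	G			14360.8596	10000.0
background	LQVYCHIHR	R	G			14943.7743	10000.0
background	SFWQCHILK	R	G			15550.3497	10000.0
background	DLMFIQWQR	R	G			16181.5464	10000.0
background	SYAMGVCHK	R	G			16838.3637	10000.0
background	FGDTNGYMR	R	G			17521.8416	10000.0
background	NWVMFTALK	R	G			18233.0622	10000.0
background	MTWYCHLLR	R	G			18973.1515	10000.0
background	LVGGLQAWK	R	G			19743.2815	10000.0
background	DDYDTALHR	R	G			20544.6715	10000.0
background	YFSTDIFDK	R	G			21378.5903	10000.0
background	YVAVIADNR	R	G			22246.3582	10000.0
background	ICTGVFASK	R	G			23149.3494	10000.0
background	EFTGGYDYR	R	G			24088.9934	10000.0
background	VYLLFITMK	R	G			25066.778	10000.0
background	NAWDMCWHR	R	G			26084.2514	10000.0
background	WDSFCHAHK	R	G			27143.0246	10000.0
background	DFVWFGFGR	R	G			28244.7739	10000.0
background	ETDDGLIAK	R	G			29391.2438	10000.0
background	VHVGWWQFR	R	G			30584.2496	10000.0
background	VILISIYHK	R	G			31825.68	10000.0
background	HASLSDCNR	R	G			33117.5007	10000.0
background	ETSNAFVLK	R	G			34461.7571	10000.0
background	QTFYEEGIR	R	G			35860.5776	10000.0
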