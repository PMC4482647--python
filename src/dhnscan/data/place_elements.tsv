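name	consensus	function	source_table
IBOXCORENT	GATAAGR	Found in light-responsive conserved DNA modular arrays	KS
SREATMSD	TTATCC	Sugar-repressive element found in genes down-regulated after main stem decapitation	KS
REBETALGLHCB21	CGGATA	Required for phytochrome regulation	KS
SITEIIBOSPCNA	TGGTCCCAC	Involved in meristematic tissue-specific expression in rice	K_n
DREDR1ATRD29AB	TACCGACAT	Response to drought, low temperature and high salinity; bound by CBF1 in Arabidopsis	K_n
LTREATLTI78	ACCGACA	Low temperature response element	K_n
ABREOSRAB21	ACGTSSSC	ABRE found in wheat and rice	K_n
ABRETAEM	GGACACGTGGC	ABRE found in wheat	SK_n
HY5AT	TGACACGTGGCA	Bound by HY5; involved in light regulation of transcriptional activity	SK_n
SGBFGMGMAUX28	TCCACGTGTC	Recognized by G-box binding factors in soybean; found in auxin-responsive genes	SK_n
GBOXLERBCS	MCACGTGGC	Sequence found in promoters of light-regulated genes	SK_n
ABREBNNAPA	CGCCACGTGTCC	ABRE found in Brassica napus	SK_n
ABREAZMRAB28	CCCACGTGGC	ABRE; ABA and water-stress responses; binding site of CBF2	SK_n
ABREMOTIFIIIOSRAB16B	GCCGCGTGGC	ABRE motif III found in rice	SK_n
LTRECOREATCOR15	CCACGTGGCC	Low temperature response element	SK_n
ABRE3HVA1	TCCACGTCTC	ABRE found in barley	SK_n
DRECRTCOREAT	RCCGAC	DRE/CRT core found in genes expressed in response to cold and dehydration	SK_n
ACIPVPAL2	CCCACCTACC	Required for vascular specific expression	SK_n
GGTCCCATGMSAUR	GGTCCCAT	Auxin response element found in soybean	SK_n
BOXCPSAS1	CTCCCAC	Involved in light-induced repression	SK_n
CBFHV	RYCGAC	CRT/DRE found in barley; bound by CBF	Y_nSK_n
ABRE2HVA22	CGCACGTGTC	ABRE2 found in barley HVA22 gene	Y_nK_n
CE3OSOSEM	AACGCGTGTC	Coupling element 3 found in rice; required for ABA induced expression	Y_nK_n
ACGTABREMOTIFA2OSEM	ACGTGKC	Core of ABRE in rice	Y_nK_n
LRENPCABE	ACGTGGCA	Positive light response element in tobacco	Y_nK_n
ABREATCONSENSUS	YACGTGGC	ABRE consensus found in Arabidopsis	Y_nK_n
ABADESI1	RTACGTGGCR	ABRE and desiccation response element in rice	Y_nK_n
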