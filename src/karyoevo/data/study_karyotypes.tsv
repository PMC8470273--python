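species	family	subfamily	tribe	diploid_number	formula	nor_pairs	source	locality	notes
Monacha sp.	Hygromiidae	Hygromiinae	Monachaini	44			this study	Portici, Naples, Italy	conflict: karyotype description gives 2n=46 (pairs 2 and 22 submetacentric, i.e. 21m+2sm); tabulated value 2n=44 retained, no formula stored; candidate new species by 16S
Trochoidea elegans	Geomitridae	Helicellinae	Trochoideini	48	16m+6sm+2t		this study	Santa Severa, Rome, Italy	pair-by-pair listing (sm pairs 1, 8-9, 12, 16-17, 21; t pairs 11, 23) implies 15m+7sm+2t; printed formula retained for distances
Trochoidea pyramidata	Geomitridae	Helicellinae	Trochoideini	48	20m+4sm		this study	Capri, Naples, Italy	pair-by-pair listing (sm pairs 1, 5, 11) implies 21m+3sm; printed formula retained for distances
Trochoidea trochoides	Geomitridae	Helicellinae	Trochoideini	48	16m+7sm+1t		this study	Fusaro, Naples, Italy	pair-by-pair listing (sm pairs 1, 3, 6, 8, 11; t pair 24) implies 18m+5sm+1t; printed formula retained for distances
Cernuella virgata	Geomitridae	Helicellinae	Cernuellini	52	24m+2sm	1	this study	Seiano, Naples, Italy	NOR loci on a single chromosome pair (ancestral condition)
Cochlicella acuta	Geomitridae	Helicellinae	Cochlicellini	52	18m+6sm+1st+1t		this study	Monte S. Angelo, Naples, Italy	haploid plates n=26; literature reports 2n=46 (Puerto de Vega, Spain): candidate independent lineages; this study's value used by default
Campylaea planospira	Helicidae	Ariantinae		60	29m+1sm		this study	Amalfi, Salerno, Italy	DNA degraded; no 16S sequence
Helix gussoneana	Helicidae	Helicinae	Helicini	54	21m+4sm+2st		this study	Petina, Salerno, Italy
Helix lucorum	Helicidae	Helicinae	Helicini	54	10m+1sm+16t		this study	Montellago, Venice, Italy	haploid plates n=27; 16 telocentric pairs
Cornu apertus	Helicidae	Helicinae	Otalini	54	22m+5sm	4	this study	Frignano, Caserta, Italy	NOR loci on four pairs (derived condition)
Eobania vermiculata	Helicidae	Helicinae	Otalini	52	24m+2sm		this study	Capri, Naples, Italy	DNA degraded; no 16S sequence
Erctella mazzullii	Helicidae	Helicinae	Otalini	54	25m+2sm		this study	Palermo, Italy
Otala lactea	Helicidae	Helicinae	Otalini	52	20m+5sm+1t	3	this study	Morocco	NOR loci on three pairs (derived condition)
Theba pisana	Helicidae	Helicinae	Thebini	60	30m		this study	Fusaro, Naples, Italy	all metacentric, gradually decreasing in length
Theba pisana	Helicidae	Helicinae	Thebini	60	30m		this study	Messina, Italy	second population; NOR and heterochromatin patterns very similar to Fusaro population
Marmorana platychela	Helicidae	Murellinae		60	28m+2sm		this study	Palermo, Italy	pairs 23 and 27 submetacentric
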