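species	family	subfamily	tribe	diploid_number	formula	nor_pairs	source	locality	notes
Leptaxinae	Hygromiidae	Leptaxinae		52			literature		inherited the hygromiid+geomitrid ancestral condition
Perforatellini	Hygromiidae	Hygromiinae	Perforatellini	48			literature		derived from 2n=52 by two translocations
Hygromiini	Hygromiidae	Hygromiinae	Hygromiini	42			literature		derived from 2n=52 by five translocations
Trochulininae	Hygromiidae	Trochulininae		46			literature		most species; derived from 2n=52 by three translocations
Xerocrassa	Geomitridae	Helicellinae	Trochoideini	50			literature		genus-level condition; spelled Xerograssa once in the source text
Trissexodontidae	Trissexodontidae			60			literature		conserves the putative ancestral karyotype
Xanthonychidae	Xanthonychidae			60			literature		conserves the putative ancestral karyotype
Caucasotachea leucoranea	Helicidae	Helicinae	Helicini	60			literature		conserves the putative ancestral karyotype
Helix straminea	Helicidae	Helicinae	Helicini	54	24m+2sm+1st		literature		reference karyotype of the Helix inversion series
Helix pomatia	Helicidae	Helicinae	Helicini	54	18m+8sm+1st		literature		six inversions from Helix straminea
Allognathini	Helicidae	Helicinae	Allognathini	44			literature		all species; derived from 2n=60 by eight translocations
Helicodonta obvoluta	Helicodontidae			54			literature		derived from 2n=60 by three translocations
Acusta ravida	Camaenidae	Bradybaeninae		58			literature		7 telocentric pairs
Bradybaena similaris	Camaenidae	Bradybaeninae		56			literature		26 telocentric pairs; one translocation from 2n=58
Cathaica fasciola	Camaenidae	Bradybaeninae		60			literature		22 telocentric pairs; one fission from 2n=58
Polygyridae typical	Polygyridae			58			literature		ancestral family condition conserved in most studied species
Allogona	Polygyridae			52			literature		two species; reduction by translocations
Vespericola columbiana	Polygyridae			60			literature		increase by fission
Cryptomastix germana	Polygyridae			62			literature		increase by fissions
Xolotrema fosteri	Polygyridae			62		1	literature		NOR loci on a single pair
Triodopsis fraudolenta	Polygyridae			62			literature		increase by fissions
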