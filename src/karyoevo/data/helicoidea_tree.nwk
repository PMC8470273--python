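(((Leptaxinae,('Monacha sp.',Perforatellini,Hygromiini)Hygromiinae,Trochulininae)Hygromiidae,('Cernuella virgata','Cochlicella acuta',(Xerocrassa,('Trochoidea elegans','Trochoidea pyramidata','Trochoidea trochoides')Trochoidea)Trochoideini)Geomitridae)'Hygromiidae-Geomitridae',Trissexodontidae,Xanthonychidae[&uncertain],(('Campylaea planospira')Ariantinae,('Marmorana platychela')Murellinae,(('Helix straminea','Helix gussoneana','Helix pomatia','Helix lucorum','Caucasotachea leucoranea')Helicini,('Cornu apertus','Eobania vermiculata','Erctella mazzullii','Otala lactea')Otalini,('Theba pisana')Thebini,Allognathini)Helicinae)Helicidae,('Helicodonta obvoluta')Helicodontidae,(('Acusta ravida','Bradybaena similaris','Cathaica fasciola')Camaenidae,('Polygyridae typical',Allogona,'Vespericola columbiana','Cryptomastix germana','Xolotrema fosteri','Triodopsis fraudolenta')Polygyridae)'Camaenidae-Polygyridae'[&uncertain])Helicoidea;
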