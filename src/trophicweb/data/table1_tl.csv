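class,order,family,species,common_name,tl
Cephalopoda,Teuthida,Loliginidae,Doryteuthis plei,Slender inshore squid,3.30
Elasmobranchii,Squaliformes,Squalidae,Squalus spp.,Dogfish,3.22
Elasmobranchii,Lamniformes,Odontaspididae,Carcharias taurus,Sand tiger shark,4.08
Elasmobranchii,Carchariniformes,Carcharinidae,Carcharhinus brevipinna,Spinner shark,3.87
Elasmobranchii,Carchariniformes,Carcharinidae,Carcharhinus leucas,Bull shark,5.00
Elasmobranchii,Carchariniformes,Carcharinidae,Prionace glauca,Blue shark,4.24
Elasmobranchii,Carchariniformes,Carcharinidae,Rhizoprionodon porosus,Carribean sharpnose shark,3.26
Elasmobranchii,Carchariniformes,Sphyrnidae,Sphyrna lewini,Scalloped hammerhead,3.82
Elasmobranchii,Rajiformes,Arhynchobatidae,Atlantoraja castelnaui,Spotback skate,4.28
Elasmobranchii,Rajiformes,Arhynchobatidae,Not discriminated,Rays,4.28
Actinopterygii,Clupeiformes,Engraulidae,Anchoviella lepidentostole,Broadband anchovy,2.88
Actinopterygii,Clupeiformes,Engraulidae,Engraulis anchoita,Argentine anchovy,2.83
Actinopterygii,Clupeiformes,Clupeidae,Brevoortia spp,Menhaden,3.10
Actinopterygii,Clupeiformes,Clupeidae,Harengula clupeola,False herring,3.05
Actinopterygii,Clupeiformes,Clupeidae,Opisthonema oglinum,Atlantic thread herring,2.61
Actinopterygii,Clupeiformes,Clupeidae,Pellona harroweri,American coastal pellona,3.33
Actinopterygii,Clupeiformes,Clupeidae,Sardinella brasiliensis,Brazilian sardine,2.77
Actinopterygii,Siluriformes,Ariidae,Family Ariidae,Catfish,3.13
Actinopterygii,Mugiliformes,Mugilidae,Mugil liza,Lebranche mullet,2.00
Actinopterygii,Beloniformes,Belonidae,Ablennes hians,Flat needlefish,5.00
Actinopterygii,Zeiformes,Zeidae,Zenopsis conchifer,Silvery John dory,3.10
Actinopterygii,Scorpaeniformes,Scorpaenidae,Helicolenus lahillei,Rosefish,4.17
Actinopterygii,Scorpaeniformes,Triglidae,Prionotus punctatus,Bluewing searobin,3.72
Actinopterygii,Perciformes,Centropomidae,Centropomus spp,Snook,3.19
Actinopterygii,Perciformes,Serranidae,Epinephelus marginatus,Dusky grouper,3.94
Actinopterygii,Perciformes,Priacanthidae,Priacanthus arenatus,Atlantic bigeye,2.99
Actinopterygii,Perciformes,Pomatomidae,Pomatomus saltatrix,Bluefish,3.60
Actinopterygii,Perciformes,Coryphaenidae,Coryphaena hippurus,Common Dolphinfish,4.44
Actinopterygii,Perciformes,Carangidae,Caranx crysos,Blue runner,3.18
Actinopterygii,Perciformes,Carangidae,Caranx hippos,Crevalle jack,3.24
Actinopterygii,Perciformes,Carangidae,Caranx latus,Horse-eye jack,3.59
Actinopterygii,Perciformes,Carangidae,Chloroscombrus chrysurus,Atlantic bumper,2.49
Actinopterygii,Perciformes,Carangidae,Oligoplites saliens,Castin leatherjacket,3.28
Actinopterygii,Perciformes,Carangidae,Parona signata,Parona leatherjacket,3.10
Actinopterygii,Perciformes,Carangidae,Selene setapinnis,Atlantic moonfish,3.28
Actinopterygii,Perciformes,Carangidae,Seriola dumerili,Greater amberjack,3.22
Actinopterygii,Perciformes,Carangidae,Trachurus lathami,Rough scad,2.77
Actinopterygii,Perciformes,Carangidae,Seriola lalandi,Yellowtail amberjack,3.39
Actinopterygii,Perciformes,Carangidae,Trachinotus carolinus,Florida pompano,2.75
Actinopterygii,Perciformes,Lutjanidae,Rhomboplites aurorubens,Vermilion snapper,3.47
Actinopterygii,Perciformes,Gerreidae,Diapterus rhombeus,Caitipa mojarra,2.82
Actinopterygii,Perciformes,Gerreidae,Eucinostomus spp.,Mojarra,3.04
Actinopterygii,Perciformes,Haemulidae,Conodon nobilis,Bared grunt,3.29
Actinopterygii,Perciformes,Haemulidae,Haemulon aurolineatum,Tomtate grunt,2.82
Actinopterygii,Perciformes,Sparidae,Archosargus probatocephalus,Sheepshead,2.88
Actinopterygii,Perciformes,Sparidae,Pagrus pagrus,Red porgy,3.83
Actinopterygii,Perciformes,Sciaenidae,Cynoscion acoupa,Acoupa weakfish,3.80
Actinopterygii,Perciformes,Sciaenidae,Cynoscion guatucupa,Stripped weakfish,3.64
Actinopterygii,Perciformes,Sciaenidae,Cynoscion jamaicensis,Jamaica weakfish,3.06
Actinopterygii,Perciformes,Sciaenidae,Cynoscion leiarchus,Smooth weakfish,3.12
Actinopterygii,Perciformes,Sciaenidae,Cynoscion microlepidotus,Smallscale weakfish,3.32
Actinopterygii,Perciformes,Sciaenidae,Cynoscion virescens,Green weakfish,3.60
Actinopterygii,Perciformes,Sciaenidae,Larimus breviceps,Shorthead drum,3.26
Actinopterygii,Perciformes,Sciaenidae,Macrodon atricauda,Southern king weakfish,3.14
Actinopterygii,Perciformes,Sciaenidae,Mentichirrhus americanus,Southern kingcroaker,3.23
Actinopterygii,Perciformes,Sciaenidae,Micropogonias furnieri,Whitemouth croaker,3.11
Actinopterygii,Perciformes,Sciaenidae,Paralonchurus brasiliensis,Banded croaker,3.14
Actinopterygii,Perciformes,Sciaenidae,Pogonias cromis,Black drum,3.34
Actinopterygii,Perciformes,Sciaenidae,Stellifer rastrifer,Rake stardrum,3.12
Actinopterygii,Perciformes,Sciaenidae,Umbrina canosai,Argentine croaker,3.11
Actinopterygii,Perciformes,Ephippidae,Chaetodipterus faber,Atlantic spadefish,2.96
Actinopterygii,Perciformes,Trichiuridae,Trichiurus lepturus,Largehead hairtail,3.21
Actinopterygii,Perciformes,Scombridae,Auxis thazard,Frigate tuna,3.50
Actinopterygii,Perciformes,Scombridae,Euthynnus alletteratus,Little tuny,3.90
Actinopterygii,Perciformes,Scombridae,Katsuwonus pelamis,Skipjack tuna,3.24
Actinopterygii,Perciformes,Scombridae,Non discriminated,Tuna fish,3.19
Actinopterygii,Perciformes,Scombridae,Scomber colias,Atlantic chub mackerel,2.99
Actinopterygii,Perciformes,Scombridae,Scomberomorus brasiliensis,Serra Spanish mackerel,3.04
Actinopterygii,Perciformes,Scombridae,Thunnus albacares,Yellowfin tuna,4.27
Actinopterygii,Perciformes,Xiphiidae,Xiphias gladius,Swordfish,3.93
Actinopterygii,Perciformes,Istiophoridae,Istiophorus albicans,Atlantic sailfish,4.19
Actinopterygii,Perciformes,Stromateidae,Peprilus paru,American harvestfish,2.77
Actinopterygii,Tetraodontiformes,Balistidae,Balistes capriscus,Grey triggerfish,3.40
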