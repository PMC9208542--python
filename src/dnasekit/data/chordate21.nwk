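(Branchiostoma_floridae:650,(Ciona_intestinalis:620,(Petromyzon_marinus:615,((Callorhinchus_milii:420,Scyliorhinus_canicula:420)Chondrichthyes:53,((Erpetoichthys_calabaricus:400,(Lepisosteus_oculatus:315,(Danio_rerio:230,Oryzias_latipes:230)Teleostei:85)Neopterygii:85)Actinopterygii:35,(Latimeria_chalumnae:413,(Xenopus_tropicalis:352,(((Anolis_carolinensis:160,Notechis_scutatus:160)Squamata:120,(Crocodylus_porosus:240,(Gallus_gallus:98,Taeniopygia_guttata:98)Aves:142)Archosauria:40)Sauropsida:32,(Ornithorhynchus_anatinus:180,(Monodelphis_domestica:160,(Canis_lupus:94,(Homo_sapiens:87,Mus_musculus:87)Euarchontoglires:7)Placentalia:66)Theria:20)Mammalia:132)Amniota:40)Tetrapoda:61)Sarcopterygii:22)Osteichthyes:38)Gnathostomata:142)Vertebrata:5)Olfactores:30)Chordata:50;
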