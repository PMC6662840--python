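(platypus:177,(Tasmanian_devil:159,(((((galago:63,sifaka:63)Strepsirrhini:11,(tarsier:67,human:67)Haplorhini:7)Primates:12,tree_shrew:86)Euarchonta:4,(mouse:46,blind_mole_rat:46)Rodentia:44)Euarchontoglires:6,((dog:45,(harbor_seal:24,(walrus:19,(fur_seal:9,sea_lion:9)Otariidae:10)Otaroidea:5)Pinnipedia:21)Carnivora:33,((alpaca:25,(dromedary:5,(bactrian_camel:1,wild_camel:1)Camelus_bw:4)Camelus:20)Camelidae:39,(cattle:62,(hippopotamus:54,(sperm_whale:32,dolphin:32)Cetacea:22)Whippomorpha:8)Artiofabula:2)Artiodactyla:14)Laurasiatheria:18)Placentalia:63)Theria:18)Mammalia;
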