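label,Azelia,Eudasyphora,Graphomya,Helina,Hydrotaea,Musca,Muscina,Mydaea,Neomyia,Phaonia,Polietes,Stomoxys,Thricops
Azelia,14,0,0,0,0,0,0,0,0,0,0,0,0
Eudasyphora,0,40,0,0,0,0,0,0,0,0,0,0,0
Graphomya,0,0,17,0,0,0,0,0,0,0,0,0,0
Helina,0,0,0,34,0,0,0,0,0,1,0,0,0
Hydrotaea,0,0,0,0,318,0,0,0,0,0,0,0,0
Musca,0,0,0,0,0,46,0,0,0,0,0,0,0
Muscina,0,0,0,0,0,0,163,0,0,0,0,0,0
Mydaea,0,0,0,0,0,0,0,14,0,0,0,0,0
Neomyia,0,0,0,0,0,0,0,0,30,0,0,0,0
Phaonia,0,0,0,0,0,0,0,1,0,44,0,0,0
Polietes,0,0,0,0,0,0,0,0,0,0,8,0,0
Stomoxys,0,0,0,0,0,0,0,0,0,0,0,32,0
Thricops,0,0,0,0,0,0,0,0,0,0,0,0,28
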