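label,H. aenescens,H. armipes,H. cyrtoneurina,H. dentipes,H. ignava,H. meteorica,H. pilipes,H. similis
H. aenescens,55,0,0,0,0,0,0,0
H. armipes,0,29,0,0,0,1,0,0
H. cyrtoneurina,0,0,28,2,0,0,0,0
H. dentipes,0,0,1,41,0,0,0,2
H. ignava,0,0,0,0,52,0,0,0
H. meteorica,0,0,0,0,0,17,1,0
H. pilipes,0,0,0,0,0,0,37,0
H. similis,0,0,0,2,0,0,0,50
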