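label,M. levida,M. pasquorum,M. prolapsa,M. stabulans
M. levida,53,0,0,0
M. pasquorum,0,30,0,0
M. prolapsa,1,0,40,1
M. stabulans,0,0,0,38
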