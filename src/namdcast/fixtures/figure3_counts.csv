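centre,month,n,n_ge70,n_lt25,n_le20
MEH,0,325,83,14,5
MEH,3,325,25,,
MEH,12,325,19,46,15
UHB,0,51,5,3,2
UHB,3,51,2,,
UHB,12,51,4,4,3
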