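centre,matched,unmatched
MEH,215,110
UHB,44,7
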