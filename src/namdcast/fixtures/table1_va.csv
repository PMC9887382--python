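cohort,n,mean,sd,median,min,max
overall,2196,55.4,16.8,59.0,0,94.0
MEH,1929,55.9,16.3,60.0,0,90.0
UHB,267,51.7,20.0,55.0,0,94.0
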