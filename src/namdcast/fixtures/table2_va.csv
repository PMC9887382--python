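cohort,n,mean,sd,median,min,max
marina_sham,238,53.61,14.06,56.0,3.0,84.0
meh_matched,215,52.92,14.45,55.0,0,86.0
meh_unmatched,110,59.50,18.36,70.0,11.0,85.0
uhb_matched,44,52.55,15.98,55.0,0,76.0
uhb_unmatched,7,40.57,20.98,35.0,11.0,80.0
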