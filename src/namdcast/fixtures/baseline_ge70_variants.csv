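source,value_type,value
results_text_count,count,83
abstract_percent,percent,25.5
table2_matched_plus_unmatched,count,77
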