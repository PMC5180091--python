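# Published summary counts for the large-protein / chromosome-organization
# analysis (the member gene lists themselves are not published, only counts).
universe_genes: 19486
high_confidence_total: 165
high_confidence_tsg: 84
high_confidence_og: 81
background_genes: 15972
medium_confidence: 682
low_confidence: 1360
large_chromatin_set_size: 92          # top-5% protein size ∩ chromosome organization
hc_tsg_inside_large_chromatin: 19
hc_og_inside_large_chromatin: 1
chromatin_modification_inside: 66
histone_modification_inside: 39
largest_driver_proteins: 30           # rows of large_driver_proteins.tsv
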