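# Default semi-universal single-copy marker KO list (72 entries).
# SYNTHETIC stand-in: near-universal single-copy orthologs that fall below
# the strict universality band (relaxed prevalence, still single copy).
K02945
K02897
K02913
K02916
K02909
K02911
K02914
K02970
K01886
K01893
K04567
K02518
K02520
K02835
K02836
K03664
K02600
K03625
K02601
K03070
K03073
K03075
K03110
K03217
K02338
K02337
K02314
K02316
K02313
K02469
K02470
K02335
K01971
K03168
K03531
K03590
K03587
K03589
K04043
K03686
K04077
K04078
K03687
K03100
K03101
K00927
K01689
K00850
K01803
K00134
K02112
K02111
K02108
K02109
K02110
K02113
K02114
K02115
K00962
K08300
K03654
K03657
K03702
K03701
K03703
K03111
K03544
K01358
K03696
K06187
K03629
K04485
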