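# Default universal single-copy marker KO list (76 entries).
# SYNTHETIC stand-in: a curated list of well-characterized universal
# single-copy orthologs (ribosomal proteins, aminoacyl-tRNA synthetases,
# translation/transcription core machinery), not derived from any specific
# genome-database snapshot. Used as the package's default normalization
# yardstick and as the marker universe of the simulator.
K02863
K02886
K02906
K02926
K02931
K02933
K02939
K02864
K02867
K02935
K02871
K02874
K02876
K02878
K02879
K02881
K02884
K02887
K02888
K02890
K02892
K02895
K02899
K02902
K02904
K02907
K02967
K02982
K02986
K02988
K02990
K02992
K02994
K02996
K02946
K02948
K02950
K02952
K02954
K02956
K02959
K02961
K02963
K02965
K02968
K01866
K01867
K01868
K01869
K01870
K01872
K01873
K01874
K01875
K01876
K01878
K01879
K01881
K01883
K01885
K01887
K01889
K01890
K01892
K02358
K02355
K02357
K02519
K02838
K03040
K03043
K03046
K03076
K03106
K03553
K01937
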