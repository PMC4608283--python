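>tRNA-iMet
AGTGCACTACACCCA
>tRNA-Lys
AGGTTCTCGAAGCCA
>tRNA-Pro
TCACCTACTGGTCCA
>tRNA-Trp
TTATTGTTACATCCA
>tRNA-Gly
CACCCGCAATTACCA
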