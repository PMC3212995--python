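>tRNA-Pro synthetic tRNA 3'-end fragment
GAGGTATTAACTGAGTGGTCTCGGTAGCGT
>tRNA-Val synthetic tRNA 3'-end fragment
CGCGCATAGCGCCGCAAGATTCATCGTTAC
>tRNA-Met synthetic tRNA 3'-end fragment
AGCGGGACCGATACTGCCCCCCGTTATCCA
>tRNA-Asn synthetic tRNA 3'-end fragment
CGATGCCTTCCCGCCAGTAGTATTCTTACG
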