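>RVT_toy1 synthetic 60-aa domain tag
HCWNMAYKEMVKYPCEFRERYAGCFHDVSQDANDSCIKHSGEHRYNQMKAKHLMPHHCGL
>RVT_toy2 synthetic 60-aa domain tag
DLIPFPVQPAGEFYWCSCYEAYNIDYQVMQTKFYLMTNGMQDMAQDWQYISYDSWVLGLY
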