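>PepA17_toy1 synthetic 60-aa domain tag
HSGLTFQEQMEFGIVKCFPWCSHDHGVWLRSWPYPPMYQRHDYMRSSISCIFPWDFQPME
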