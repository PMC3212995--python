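>RVE_toy1 synthetic 60-aa domain tag
ELHKWYYWVTINYWMARIWGHSMGWFYHEGSPAPTWFRFGCFFNHKPWLDQHYDCNNQCN
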