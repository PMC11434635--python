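,BPM,BH,F,EP
BPM,1,3,6,8
BH,1/3,1,3,4
F,1/6,1/3,1,2
EP,1/8,1/4,1/2,1
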