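,BPM,BH,F,EP
BPM,1,6,8,9
BH,1/6,1,4,6
F,1/8,1/4,1,4
EP,1/9,1/6,1/4,1
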