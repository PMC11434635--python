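,GC,ND,P,C
GC,1,4,6,8
ND,1/4,1,2,4
P,1/6,1/2,1,2
C,1/8,1/4,1/2,1
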