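,GC,ND,P,C
GC,1,6,8,9
ND,1/6,1,3,5
P,1/8,1/3,1,4
C,1/9,1/5,1/4,1
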