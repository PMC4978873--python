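village,class,households_total,households_sampled,charcoal,firewood,construction,grass,food,medicine,livestock
A,post-boom,38,34,29,33,19,9,9,2,12
B,post-boom,29,25,22,25,18,12,3,5,15
C,post-boom,63,51,46,49,25,30,10,11,12
D,boom,42,36,23,31,21,18,10,7,5
E,boom,58,42,21,42,24,5,4,5,27
F,pre-boom,55,48,42,48,38,9,6,6,29
G,pre-boom,27,24,0,24,14,7,6,4,16
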