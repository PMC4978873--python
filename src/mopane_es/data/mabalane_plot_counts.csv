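village,class,Androstachys forest,Mopane woodland,Combretum woodland,Boscia woodland,shrub Mopane
A,post-boom,0,3,4,13,3
B,post-boom,0,19,4,0,0
C,post-boom,0,11,9,0,0
D,boom,6,1,12,0,0
E,boom,5,1,17,0,0
F,pre-boom,7,14,2,0,0
G,pre-boom,6,2,15,0,0
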