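village,class,charcoal,firewood,construction,food,medicine,grass
A,post-boom,decline,decline,decline,no_change,no_change,no_change
B,post-boom,decline,no_change,decline,no_change,no_change,no_change
C,post-boom,decline,no_change,decline,no_change,no_change,no_change
D,boom,decline,decline,decline,no_change,no_change,no_change
E,boom,no_change,no_change,decline,no_change,no_change,no_change
F,pre-boom,no_change,no_change,no_change,no_change,no_change,no_change
G,pre-boom,not_applicable,no_change,no_change,no_change,no_change,no_change
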