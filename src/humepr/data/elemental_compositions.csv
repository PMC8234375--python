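# CHNO composition of the four humic-acid samples, atomic percent.
# RT_1/RT_3: forest-soil humic acids (organic / mineral horizon);
# G_0: incubated wheat plant material; F_1: plant material mixed with soil.
label,C,H,N,O
RT_1,35.58,44.20,1.12,19.10
RT_3,33.22,44.88,1.93,19.97
G_0,36.31,48.36,1.10,14.23
F_1,37.28,45.27,1.61,15.84
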