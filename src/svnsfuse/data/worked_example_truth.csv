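instance,label
1,NV
2,MEL
3,MEL
4,MEL
5,MEL
6,BKL
7,BKL
8,BCC
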