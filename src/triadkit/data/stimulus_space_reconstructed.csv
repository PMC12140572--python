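stimulus,chroma,brightness
1,4,5
2,12,6
3,6,5
4,8,6
5,6,3
6,10,3
7,4,2
8,12,2
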