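stimulus,1,2,3,4,5,6,7,8
1,,4.32,7.68,5.03,4.47,3.78,3.81,3.57
2,4.32,,4.54,7.12,3.07,3.33,2.36,2.97
3,7.68,4.54,,6.38,5.90,4.79,4.71,3.92
4,5.03,7.12,6.38,,4.28,4.65,3.27,3.95
5,4.47,3.07,5.90,4.28,,6.60,7.66,5.61
6,3.78,3.33,4.79,4.65,6.60,,5.66,7.34
7,3.81,2.36,4.71,3.27,7.66,5.66,,5.33
8,3.57,2.97,3.92,3.95,5.61,7.34,5.33,
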