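N,Y_leaf,Y_stem,Y_fruit,Y_stemfruit
0,1.51,1.72,5.21,6.93
56,1.55,1.74,5.25,6.99
112,1.56,1.96,5.63,7.59
168,1.99,2.48,6.37,8.85
224,2.12,2.49,6.97,9.46
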