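t,Y_leaf,Y_stem,Y_fruit
21.2,,,
21.9,0.39,0.32,
26.4,1.52,1.74,0.91
30.1,1.83,2.35,4.25
35.1,1.99,2.48,6.37
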