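t,Y_total,Nu,Pu,Ku
21.2,,,,
21.6,0.35,16,1.5,9
23.7,1.0,40,3.4,20
25.9,2.7,80,7.7,60
28.0,4.6,120,7.4,90
30.3,5.7,130,15,100
32.4,6.6,140,15,90
34.7,7.8,135,16,110
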