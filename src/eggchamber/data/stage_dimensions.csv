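stage,time_hr,L_E,L_O,L_FC,W_E,W_O,sd_L_E,sd_L_O,sd_L_FC,sd_W_E,sd_W_O
S7,3,71,,71,45,,2.1,,2.1,2.1,
S8E,7.5,99,19,99,61,46,2.5,1.1,2.5,2.9,2.7
S8L,10.5,132,31,132,74,58,3.7,1.2,3.7,2.8,1.8
S9E,13.5,190,63,127,96,90,4.5,3.7,5.4,3.2,3.7
S9L,16.5,246,111,131,102,100,5.9,3.1,4.5,2.8,2.6
S10A,19.5,307,149,149,129,129,7.9,3.2,3.2,4.3,4.3
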