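,MEL,BCC,AKIEC,BKL,NV,DF,VASC
MEL,4,0,0,-8,-8,-8,-8
BCC,1,4,1,-4,-4,-4,-4
AKIEC,1,1,4,-3,-3,-3,-3
BKL,-2,-1,-1,2,0,0,0
NV,-2,-1,-1,0,2,0,0
DF,-2,-1,-1,0,0,2,0
VASC,-2,-1,-1,0,0,0,2
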