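,DISMISS,MONITOR,EXCISE
MEL,-8,-2,4
BCC,-6,-2,4
AKIEC,-4,-1,3
BKL,1,0,-3
NV,1,0,-3
DF,1,0,-3
VASC,1,0,-3
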