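,DISMISS,EXCISE
MEL,-6,4
BCC,-5,4
AKIEC,-4,3
BKL,1,-1
NV,1,-1
DF,1,-1
VASC,1,-1
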