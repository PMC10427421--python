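,DISMISS,TREAT_LOCALLY,EXCISE
MEL,-8,-4,4
BCC,-5,1,4
AKIEC,-4,4,1
BKL,1,-1,-2
NV,1,-1,-2
DF,1,-1,-2
VASC,1,-1,-2
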