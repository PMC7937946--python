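S100A8
S100A9
FCGR3B
CSF3R
MMP9
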