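sample_id,group
DY_1,DY
DM_1,DM
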