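item,fraction
zooplankton,0.703
phytoplankton,0.297
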