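region,lutetium-177
right kidney,1.6000
left kidney,1.6000
spleen,2.5000
liver,15.2000
RBM,0.3000
remainder,12.5000
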