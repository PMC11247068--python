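region,lutetium-177,scandium-44,scandium-44m,scandium-43,gallium-68
right kidney,1.6000,0.0406,0.6000,0.0405,0.0120
left kidney,1.6000,0.0406,0.6000,0.0405,0.0120
spleen,2.5000,0.0635,0.9375,0.0633,0.0180
liver,15.2000,0.3859,5.7000,0.3849,0.1120
RBM,0.3000,0.0076,0.1125,0.0076,0.0020
remainder,12.5000,0.3174,4.6875,0.3166,0.0920
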