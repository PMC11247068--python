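phantom,nuclide,effective_dose_mSv_per_MBq,effective_dose_sd,kidneys_mGy_per_MBq,liver_mGy_per_MBq,RBM_mGy_per_MBq,spleen_mGy_per_MBq
AF,scandium-43,1.1E-2,5.7E-6,8.9E-2,9.0E-2,5.6E-3,1.3E-1
AF,scandium-44,2.0E-2,9.6E-5,1.4E-1,1.4E-1,1.0E-2,2.0E-1
AF,scandium-44m,2.9E-2,2.5E-5,1.6E-1,1.8E-1,1.8E-2,2.2E-1
AF,gallium-68,4.5E-3,1.6E-5,4.0E-2,4.0E-2,2.0E-3,6.0E-2
AM,scandium-43,9.2E-3,1.2E-5,7.8E-2,7.2E-2,4.4E-3,1.2E-1
AM,scandium-44,1.6E-2,2.5E-5,1.2E-1,1.2E-1,8.3E-3,1.8E-1
AM,scandium-44m,2.5E-2,6.8E-5,1.5E-1,1.5E-1,1.5E-2,2.0E-1
AM,gallium-68,3.6E-3,1.4E-5,3.5E-2,3.1E-2,1.5E-3,5.3E-2
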