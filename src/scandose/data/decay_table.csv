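nuclide,half_life_value,half_life_unit,radiation_class,yield_per_decay,mean_energy_MeV,provenance_note
scandium-43,3.89,h,gamma,2.3E-01,3.7E-01,
scandium-43,3.89,h,xray,4.6E-01,1.7E-04,
scandium-43,3.89,h,annihilation_photon,1.8E+00,5.1E-01,
scandium-43,3.89,h,beta_plus,8.8E-01,4.8E-01,
scandium-43,3.89,h,internal_conversion_electron,1.3E-04,3.7E-01,
scandium-43,3.89,h,auger_electron,3.2E-01,1.1E-03,
scandium-44,4.04,h,gamma,1.0E+00,1.2E+00,
scandium-44,4.04,h,xray,2.2E-01,1.7E-04,
scandium-44,4.04,h,annihilation_photon,1.9E+00,5.1E-01,
scandium-44,4.04,h,beta_plus,9.4E-01,6.3E-01,
scandium-44,4.04,h,internal_conversion_electron,6.5E-05,1.2E+00,
scandium-44,4.04,h,auger_electron,1.5E-01,1.1E-03,
scandium-44m,58.7,h,gamma,9.0E-01,3.0E-01,
scandium-44m,58.7,h,xray,9.9E-01,1.0E-04,printed 'l.0E-04'; curated l->1
scandium-44m,58.7,h,internal_conversion_electron,1.2E-01,2.7E-01,
scandium-44m,58.7,h,auger_electron,8.3E-01,5.3E-04,printed 'S.3E-04'; curated S->5
lutetium-177,6.64,d,gamma,1.8E-01,1.8E-01,
lutetium-177,6.64,d,xray,1.4E+00,2.6E-03,printed '1.4E+0D'; curated D->0 (flagged: verify against ICRP 107)
lutetium-177,6.64,d,beta_minus,1.0E+00,1.3E-01,
lutetium-177,6.64,d,internal_conversion_electron,1.5E-01,8.7E-02,
lutetium-177,6.64,d,auger_electron,1.1E+00,1.0E-03,
gallium-68,68,min,gamma,3.6E-02,1.1E+00,
gallium-68,68,min,xray,5.7E-01,7.2E-04,
gallium-68,68,min,annihilation_photon,1.8E+00,5.1E-01,
gallium-68,68,min,beta_plus,8.9E-01,8.3E-01,
gallium-68,68,min,internal_conversion_electron,9.3E-06,1.1E+00,
gallium-68,68,min,auger_electron,4.1E-01,1.3E-03,
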