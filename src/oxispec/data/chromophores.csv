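wavelength_nm,eps_hb,eps_hbo2
450,103.292,62.816
500,20.862,20.932
550,53.412,43.016
570,45.072,44.496
600,14.677,3.200
610,9.443,1.506
650,3.750,0.368
680,2.407,0.276
730,1.102,0.390
760,1.548,0.586
810,0.717,0.864
860,0.726,1.058
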