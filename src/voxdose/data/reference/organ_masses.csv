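# reference organ masses: OLINDA 25 g mouse vs the two voxel phantom builds
# units: masses in g, differences in % relative to the OLINDA mass
# version: 1
organ,olinda_g,lr_g,lr_pct_diff,hr_g,hr_pct_diff
Heart,0.235,0.388,65.0,0.308,31.1
Liver,1.74,1.87,7.89,1.80,3.50
Lungs,0.087,0.115,32.6,0.124,42.0
Stomach wall,0.055,0.066,19.1,0.068,22.2
Pancreas,0.305,0.371,21.7,0.347,13.7
Kidneys,0.302,0.364,20.5,0.330,9.46
Spleen,0.111,0.134,20.5,0.107,-3.40
Small intestine,1.74,0.998,-42.7,0.984,-43.5
Large intestine,0.583,0.308,-47.3,0.308,-47.1
Bladder,0.060,0.071,18.7,0.064,6.66
Testes,0.160,0.380,137,0.324,102
Brain,0.466,0.559,20.1,0.489,5.01
Thyroid,0.014,0.015,7.95,0.013,-9.59
Skeleton,2.18,3.33,52.6,2.51,15.0
Total body,24.1,26.2,8.57,25.2,4.46
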