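# reference bone-marrow-targeted S-values: published comparison set
# units: S in Gy Bq^-1 s^-1; pct_diff = 100*(s_phantom - s_reference)/s_reference
# note: provenance columns kept as published; the BM<-BM LR entry here (1.16e-11)
#       differs from the 1.57e-11 printed in the LR organ-organ table of the same
#       study; both are retained rather than reconciled.
# version: 1
source_organ,s_reference,s_lr,lr_pct_diff,s_hr,hr_pct_diff
Liver,1.11e-14,1.66e-14,49.7,3.16e-15,-71.6
Kidneys,3.52e-15,3.74e-15,6.2,1.93e-15,-45.1
Spleen,1.53e-14,1.43e-14,-6.6,5.92e-15,-61.4
BM,8.40e-11,1.16e-11,-86.2,1.07e-11,-87.3
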