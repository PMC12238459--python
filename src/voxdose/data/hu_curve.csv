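# default HU <-> linear attenuation calibration nodes at 140 keV
# (piecewise-linear, strictly monotone in mu; swappable via config)
# units: hu [Hounsfield], mu [1/cm]
# version: 1
hu,mu
-1000,0.000187
-700,0.0455
0,0.1535
1600,0.3000
3000,0.5000
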