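# source: NIST XCOM photoelectric mass attenuation coefficients, liquid water
# units: energy_kev [keV], pe_mass [cm^2/g]
# version: 1
# note: incoherent scattering is computed analytically from the Klein-Nishina
#       cross section (free-electron approximation); coherent scattering neglected.
energy_kev,pe_mass
10.0,4.944
15.0,1.374
20.0,0.5390
30.0,0.1505
40.0,0.06010
50.0,0.02970
60.0,0.01670
80.0,0.00663
100.0,0.00327
150.0,0.000923
200.0,0.000374
300.0,0.000105
400.0,4.30e-05
500.0,2.20e-05
600.0,1.30e-05
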