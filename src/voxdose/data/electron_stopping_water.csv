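# source: ICRU-37 / NIST ESTAR collision stopping powers for liquid water
# units: energy_kev [keV], stopping_power [MeV cm^2 / g]
# version: 1
# note: radiative losses excluded (bremsstrahlung neglected at Lu-177 energies)
energy_kev,stopping_power
1.0,126.2
1.5,96.40
2.0,77.47
3.0,56.72
4.0,45.60
5.0,38.45
6.0,33.40
8.0,26.67
10.0,22.56
15.0,16.47
20.0,13.17
30.0,9.653
40.0,7.781
50.0,6.603
60.0,5.797
70.0,5.207
80.0,4.757
90.0,4.402
100.0,4.115
125.0,3.591
150.0,3.238
175.0,2.984
200.0,2.793
250.0,2.528
300.0,2.355
350.0,2.233
400.0,2.148
450.0,2.083
500.0,2.034
600.0,1.963
700.0,1.920
800.0,1.886
1000.0,1.849
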