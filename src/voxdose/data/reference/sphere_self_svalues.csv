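# reference tumour (unit-density sphere) self-dose S-values, by nominal mass
# resolution: hr = 0.29 mm voxels, lr = 0.625 mm voxels
# units: S in Gy MBq^-1 s^-1; pct_diff = 100*(s_sim - s_olinda)/s_olinda
# version: 1
mass_g,resolution,s_olinda,s_sim,pct_diff
0.12,hr,1.83e-04,1.82e-04,-0.69
0.13,lr,1.66e-04,1.64e-04,-1.10
0.22,hr,9.51e-05,9.51e-05,-0.01
0.26,lr,8.33e-05,8.30e-05,-0.29
0.33,hr,6.42e-05,6.44e-05,0.26
0.37,lr,5.76e-05,5.76e-05,0.02
0.44,hr,4.88e-05,4.90e-05,0.38
0.48,lr,4.43e-05,4.44e-05,0.18
0.54,hr,3.95e-05,3.97e-05,0.46
0.60,lr,3.58e-05,3.59e-05,0.27
0.65,hr,3.31e-05,3.33e-05,0.51
0.71,lr,3.02e-05,3.03e-05,0.33
0.75,hr,2.86e-05,2.87e-05,0.54
0.81,lr,2.64e-05,2.65e-05,0.35
0.86,hr,2.51e-05,2.52e-05,0.56
0.93,lr,2.31e-05,2.32e-05,0.39
0.96,hr,2.24e-05,2.25e-05,0.57
1.04,lr,2.07e-05,2.08e-05,0.39
1.07,hr,2.02e-05,2.03e-05,0.57
1.15,lr,1.88e-05,1.89e-05,0.42
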