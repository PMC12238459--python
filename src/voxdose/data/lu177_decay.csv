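# source: evaluated Lu-177 decay data (DDEP/LNHB-style line list, Hf-177 daughter)
# units: energy_kev [keV] (endpoint for beta branches), intensity [per decay],
#        mean_kev [keV] (evaluated branch mean, beta branches only; blank otherwise)
# version: 1
# note: beta branch shapes are Fermi distributions with a linear shape correction
#       calibrated so each branch reproduces its listed mean energy.  Branch means
#       are the DDEP values scaled by 0.9934 so the intensity-weighted aggregate
#       matches the ICRP-107 mean beta energy of 133.3 keV per decay.
kind,energy_kev,intensity,mean_kev
beta_branch,497.8,0.7930,148.41
beta_branch,384.7,0.0910,111.16
beta_branch,176.5,0.1161,47.48
conversion_electron,47.64,0.0700,
conversion_electron,103.40,0.0450,
conversion_electron,111.20,0.0140,
conversion_electron,143.09,0.0050,
conversion_electron,198.58,0.0008,
auger,6.20,0.1000,
auger,43.00,0.0016,
gamma,71.64,0.00154,
gamma,112.95,0.0617,
gamma,136.72,0.00047,
gamma,208.37,0.1038,
gamma,249.67,0.00212,
gamma,321.32,0.00216,
xray,54.61,0.0210,
xray,55.79,0.0370,
xray,63.23,0.0130,
xray,7.90,0.0260,
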