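gas,horizon_yr,factor
CO2,20,0.190
CO2,100,1
CO2,500,4.71
CH4_fossil,20,15.7
CH4_fossil,100,29.8
CH4_fossil,500,47.1
CH4_nonfossil,20,15.1
CH4_nonfossil,100,27.0
CH4_nonfossil,500,33.9
N2O,20,51.8
N2O,100,273
N2O,500,612
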