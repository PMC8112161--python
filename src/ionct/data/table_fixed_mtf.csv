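ion,E_init,range_cm,mtf10,sigma_wet,sigma_wet_err,g_ph,g_ph_err,g_dt,g_dt_err,S_MC,S_MC_err,E_out
proton,350.0,66.2,10.0,4.50,0.17,1.11,0.09,1.52,0.23,0.77,0.03,281.4
helium,191.1,24.1,10.7,1.20,0.05,1.28,0.17,1.14,0.11,5.5,0.23,70.0
lithium,234.6,22.8,12.9,0.92,0.04,1.42,0.21,1.13,0.10,9.75,0.41,70.3
boron,309.6,21.7,16.5,0.67,0.03,1.55,0.23,1.09,0.08,13.82,0.57,71.4
carbon,343.1,21.4,18.0,0.61,0.03,1.61,0.24,1.08,0.07,15.47,0.61,70.9
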