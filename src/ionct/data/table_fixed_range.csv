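ion,E_init,sigma_wet,sigma_wet_err,g_ph,g_ph_err,g_dt,g_dt_err,S_MC,S_MC_err,E_out
proton,200.0,2.52,0.10,1.12,0.10,1.08,0.07,1.13,0.05,87.0
helium,200.0,1.26,0.06,1.28,0.17,1.20,0.14,4.86,0.21,87.0
lithium,253.9,1.01,0.05,1.40,0.20,1.27,0.17,8.33,0.36,108.9
boron,345.7,0.75,0.04,1.53,0.23,1.32,0.18,11.16,0.52,145.5
carbon,386.9,0.66,0.04,1.59,0.23,1.34,0.19,13.18,0.55,161.5
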