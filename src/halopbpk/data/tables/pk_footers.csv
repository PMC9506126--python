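# Printed predictability-assessment footers (MFE and RMSE per route and
# parameter) of the published evaluation tables.
route,parameter,mfe_printed,rmse_printed
iv,AUC_inf,0.91,46.2
iv,Cmax,1.00,6.76
iv,CL,1.01,1.38
oral,AUC_inf,0.99,27.27
oral,Cmax,1.03,1.66
oral,CL,0.99,1.96
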