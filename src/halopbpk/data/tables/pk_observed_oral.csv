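# Predicted and observed PK parameters after oral administration
# (published model-evaluation table); columns as in pk_observed_iv.csv.
scenario_id,parameter,predicted,observed,ratio_printed,pe_printed_pct,observed_pksolver
oral_0503mgkg_healthy,AUC_inf,537.4,566,0.95,5.1,0
oral_0503mgkg_healthy,Cmax,33.60,37.4,0.90,10.2,1
oral_0503mgkg_healthy,CL,15.61,15.41,1.01,1.3,1
oral_05mgkg_healthy,AUC_inf,544,500.1,1.10,8.8,1
oral_05mgkg_healthy,Cmax,35.34,35.83,0.99,1.3,1
oral_05mgkg_healthy,CL,15.20,16.64,0.91,8.7,1
oral_05mgkg_psychotic,AUC_inf,550,512.6,1.07,7.3,0
oral_05mgkg_psychotic,Cmax,20.81,19.76,1.05,5.3,1
oral_05mgkg_psychotic,CL,15.12,15.73,0.96,3.9,1
oral_10mg_psychotic,AUC_inf,212.8,200.5,1.06,6.1,0
oral_10mg_psychotic,Cmax,9.13,8.34,1.08,9.5,1
oral_10mg_psychotic,CL,15,18.2,0.82,17.6,0
oral_5mg_healthy,AUC_inf,40.10,44,0.91,8.9,1
oral_5mg_healthy,Cmax,1.28,1.27,1.01,0.8,1
oral_5mg_healthy,CL,29.0,25.85,1.12,12.2,1
oral_2mg_psychotic,AUC_inf,90.73,103,0.88,12,1
oral_2mg_psychotic,Cmax,3.95,3.54,1.12,11.6,1
oral_2mg_psychotic,CL,5.50,4.93,1.12,11.7,1
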