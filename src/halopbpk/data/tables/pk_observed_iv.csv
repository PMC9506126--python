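# Predicted and observed PK parameters after intravenous administration
# (published model-evaluation table). ratio_printed / pe_printed_pct are the
# table's own derived cells; observed_pksolver marks observed values that
# were re-derived with an NCA tool rather than transcribed from the study.
scenario_id,parameter,predicted,observed,ratio_printed,pe_printed_pct,observed_pksolver
iv_0125mgkg_healthy_a,AUC_inf,168,202,0.83,17,0
iv_0125mgkg_healthy_a,Cmax,28,27,1.04,4,1
iv_0125mgkg_healthy_a,CL,12.3,11.1,1.11,9.3,0
iv_0125mgkg_healthy_b,AUC_inf,171.3,173.3,1.01,1.2,1
iv_0125mgkg_healthy_b,Cmax,32.5,32.5,1.00,0.00,1
iv_0125mgkg_healthy_b,CL,12.0,12.02,0.99,0.00,1
iv_0125mgkg_psychotic,AUC_inf,271,383,0.71,6.3,0
iv_0125mgkg_psychotic,Cmax,77.22,63.10,1.22,22.4,1
iv_0125mgkg_psychotic,CL,7.56,6.20,1.22,21.9,0
iv_10mg_healthy,AUC_inf,193,202,0.96,4.5,1
iv_10mg_healthy,Cmax,31.50,25.70,1.21,23,1
iv_10mg_healthy,CL,12.20,11.90,1.03,2.5,1
iv_5mg_psychotic,AUC_inf,97.56,86.20,1.13,13.2,1
iv_5mg_psychotic,Cmax,108.70,115,0.95,5.5,1
iv_5mg_psychotic,CL,10,13,0.77,23,1
iv_3p5mg_psychotic,AUC_inf,144.30,175.72,0.82,18,1
iv_3p5mg_psychotic,Cmax,15.13,19.2,0.79,21.2,1
iv_3p5mg_psychotic,CL,6.30,6.50,0.97,3.1,0
iv_2p5mg_healthy,AUC_inf,56,60.40,0.93,7.3,0
iv_2p5mg_healthy,Cmax,22.00,27.43,0.80,19.8,1
iv_2p5mg_healthy,CL,10.62,11.55,0.92,8.2,1
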