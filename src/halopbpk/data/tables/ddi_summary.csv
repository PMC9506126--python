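# Published comparison of haloperidol PK with and without the CYP3A4
# inducer rifampicin (5 mg IV, tuberculotic population).
# fold_error = max(ratio, 1/ratio) of predicted vs observed, as printed.
group,quantity,predicted,observed,fold_error_printed
control,AUC_inf,174,186.1,0.93
control,T_half,11.5,10.1,1.22
rifampicin,AUC_inf,103.85,105.03,0.99
rifampicin,T_half,4.76,4.93,0.97
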