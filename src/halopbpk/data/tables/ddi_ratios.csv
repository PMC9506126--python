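# Printed predicted interaction ratios (rifampicin arm / control arm).
quantity,ratio_printed
AUC_inf,0.60
T_half,0.41
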