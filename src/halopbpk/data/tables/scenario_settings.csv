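# Model-side simulation settings per scenario (package assumptions, not
# study-reported values).
# weight_mean_kg: representative body weight for the mean individual (study
#   mean where reported, midpoint of the reported range otherwise, the
#   70 kg reference where no demographics were reported).
# first_sample_h: start of the observed sampling window used for NCA on
#   simulated profiles. Reconstructed a priori from the apparent volume
#   Dose/Cmax_observed of each IV study (an early first sample sees the
#   pre-distribution concentration; a late one the post-distribution one);
#   oral studies use a nominal 0.25 h first sample.
# duration_h: simulated duration; lambda_z_points: terminal-fit samples.
scenario_id,weight_mean_kg,first_sample_h,duration_h,lambda_z_points,tb,rifampicin
iv_0125mgkg_healthy_a,70.5,0.5,48,4,0,0
iv_0125mgkg_healthy_b,74,0.5,48,4,0,0
iv_0125mgkg_psychotic,63.3,0.25,48,4,0,0
iv_10mg_healthy,70,0.5,48,4,0,0
iv_5mg_psychotic,74,0.083,48,4,0,0
iv_5mg_tb_control,70,0.25,48,4,1,0
iv_5mg_tb_rifampicin,70,0.25,48,4,1,1
iv_3p5mg_psychotic,67,0.25,48,4,0,0
iv_2p5mg_healthy,72.5,0.167,48,4,0,0
rhal_after_iv_0125mgkg,63.3,0.25,48,4,0,0
oral_0503mgkg_healthy,70.8,0.25,48,4,0,0
oral_05mgkg_healthy,74,0.25,48,4,0,0
oral_05mgkg_psychotic,63.3,0.25,48,4,0,0
oral_10mg_psychotic,54.5,0.25,48,4,0,0
oral_5mg_healthy,71.5,0.25,48,4,0,0
oral_2mg_psychotic,67,0.25,48,4,0,0
rhal_after_oral_05mgkg,63.3,0.25,48,4,0,0
rhal_oral_10mg,54.5,0.25,48,4,0,0
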