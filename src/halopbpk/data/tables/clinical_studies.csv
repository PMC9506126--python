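# Clinical PK studies used to build and evaluate the model (study catalog).
# dose_unit: mg or mg_per_kg; measured: the analyte reported by the study.
scenario_id,compound_dosed,measured,route,dose_value,dose_unit,n,n_female,age,weight,population
iv_0125mgkg_healthy_a,haloperidol,haloperidol,iv-bolus,0.125,mg_per_kg,6,0,21-37,mean 70.5,healthy
iv_0125mgkg_healthy_b,haloperidol,haloperidol,iv-bolus,0.125,mg_per_kg,12,0,19-37,56-92,healthy
iv_0125mgkg_psychotic,haloperidol,haloperidol,iv-bolus,0.125,mg_per_kg,8,0,21-48,mean 63.3,psychotic otherwise healthy
iv_10mg_healthy,haloperidol,haloperidol,iv-bolus,10,mg,12,0,,,healthy
iv_5mg_psychotic,haloperidol,haloperidol,iv-bolus,5,mg,1,1,mean 55,74,psychotic otherwise healthy
iv_5mg_tb_control,haloperidol,haloperidol,iv-bolus,5,mg,2,,20s-60s,,tuberculotic (control)
iv_5mg_tb_rifampicin,haloperidol,haloperidol,iv-bolus,5,mg,3,,20s-60s,,tuberculotic (intervention)
iv_3p5mg_psychotic,haloperidol,haloperidol,iv-bolus,3.5,mg,6,3,20-43,mean 67,psychotic otherwise healthy
iv_2p5mg_healthy,haloperidol,haloperidol,iv-bolus,2.5,mg,4,2,24-37,63-82,healthy
rhal_after_iv_0125mgkg,haloperidol,reduced haloperidol,iv-bolus,0.125,mg_per_kg,8,0,21-48,mean 63.3,psychotic otherwise healthy
oral_0503mgkg_healthy,haloperidol,haloperidol,oral,0.503,mg_per_kg,8,0,19-37,mean 70.8,healthy
oral_05mgkg_healthy,haloperidol,haloperidol,oral,0.500,mg_per_kg,9,0,19-37,56-92,healthy
oral_05mgkg_psychotic,haloperidol,haloperidol,oral,0.500,mg_per_kg,6,0,21-48,mean 63.3,psychotic otherwise healthy
oral_10mg_psychotic,haloperidol,haloperidol,oral,10,mg,6,0,32-57,43-66,psychotic otherwise healthy
oral_5mg_healthy,haloperidol,haloperidol,oral,5,mg,28,0,18-50,mean 71.5,healthy
oral_2mg_psychotic,haloperidol,haloperidol,oral,2,mg,8,5,mean 32,mean 67,psychotic otherwise healthy
rhal_after_oral_05mgkg,haloperidol,reduced haloperidol,oral,0.500,mg_per_kg,6,0,21-48,63.3 +/- 6.7,psychotic otherwise healthy
rhal_oral_10mg,reduced haloperidol,reduced haloperidol,oral,10,mg,6,0,32-57,43-66,psychotic otherwise healthy
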