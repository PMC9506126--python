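# Tissue composition constants for tissue-to-plasma partitioning of
# moderate-to-strong bases, after Rodgers, Leahy & Rowland (2005,
# J Pharm Sci 94:1259) and Rodgers & Rowland (2006, J Pharm Sci 95:1238).
# f_water_extracellular / f_water_intracellular: fractional tissue water
# f_neutral_lipid / f_neutral_phospholipid: fractional lipid content
# acidic_phospholipid_mg_g: acidic phospholipid concentration (mg/g tissue)
# blood_cells row: erythrocytes (intracellular pH 7.22); used to
# back-calculate the acidic-phospholipid association constant.
tissue,f_water_extracellular,f_water_intracellular,f_neutral_lipid,f_neutral_phospholipid,acidic_phospholipid_mg_g
adipose,0.135,0.017,0.853,0.0016,0.40
bone,0.100,0.346,0.017,0.0017,0.67
brain,0.162,0.620,0.039,0.0015,0.40
gut,0.282,0.475,0.038,0.0125,2.41
stomach,0.320,0.475,0.038,0.0125,2.41
heart,0.320,0.456,0.014,0.0111,2.25
kidney,0.273,0.483,0.012,0.0240,5.03
liver,0.161,0.573,0.014,0.0240,4.56
lung,0.336,0.446,0.022,0.0128,3.91
muscle,0.118,0.630,0.010,0.0072,1.53
pancreas,0.120,0.664,0.041,0.0093,0.41
skin,0.382,0.291,0.060,0.0044,1.32
spleen,0.207,0.579,0.0077,0.0113,3.18
blood_cells,0.0,0.603,0.0017,0.0029,0.50
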