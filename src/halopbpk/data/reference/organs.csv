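# Reference adult physiology (male, ~70 kg, ~176 cm), assembled from standard
# reference-human compilations: organ volumes after ICRP Publication 89 and
# Valentin (2002); regional blood flows as fractions of cardiac output after
# Williams & Leggett (1989, Clin Phys Physiol Meas 10:187) and Davies &
# Morris (1993, Pharm Res 10:1093). Cardiac output 5.6 L/min = 336 L/h.
# volume_l: anatomical volume (density ~1 g/mL assumed)
# flow_fraction: organ arterial inflow / cardiac output
# portal: 1 if venous outflow drains to the liver via the portal vein
# composition: key into tissue_composition.csv
organ,volume_l,flow_fraction,portal,composition
adipose,13.5,0.050,0,adipose
bone,7.0,0.050,0,bone
brain,1.45,0.120,0,brain
gut,1.20,0.140,1,gut
stomach,0.15,0.010,1,stomach
spleen,0.19,0.020,1,spleen
pancreas,0.14,0.010,1,pancreas
heart,0.33,0.040,0,heart
kidney,0.31,0.190,0,kidney
liver,1.80,0.065,0,liver
lung,0.53,1.000,0,lung
muscle,28.0,0.170,0,muscle
skin,3.30,0.050,0,skin
rest,3.40,0.085,0,muscle
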