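# Haloperidol drug-dependent parameter set.
# Km values are the binding-corrected inputs actually used by the model
# (apparent Km x fu,inc where an apparent value is given); vmax values are
# in the unit stated per pathway, recombinant rates carry an ISEF.

name = "haloperidol"
molecular_weight = 376.0          # g/mol
effective_molecular_weight = 336.86
log_p = 3.66
pka = 8.65
ionization = "monoprotic-base"
water_solubility_mg_ml = 0.0045
fraction_unbound = 0.085
intestinal_permeability_cm_min = 3.09e-4
gfr_fraction = 1.0                # renal filtration clearance = 1.0 x GFR x fu
fu_incubation = 0.35
blood_plasma_ratio = 1.0
additional_hepatic_clearance_ml_min_kg = 0.0

[[pathway]]
enzyme = "CYP3A4"
reaction = "N-dealkylation to 4-FBPA"
system = "HLM"
km_apparent_umol_l = 62.0
km_umol_l = 21.7
vmax = 289.0
vmax_unit = "pmol/min/mg"
localization = "microsomal"
product = "sink"

[[pathway]]
enzyme = "CYP3A4"
reaction = "oxidation to HPP+"
system = "HLM"
km_apparent_umol_l = 80.0
km_umol_l = 28.0
vmax = 243.8                      # 0.53 pmol/min/pmol CYP x 460 pmol CYP/mg
vmax_unit = "pmol/min/mg"
localization = "microsomal"
product = "sink"

[[pathway]]
enzyme = "CBR1"
reaction = "carbonyl reduction to reduced haloperidol"
system = "HLC"
km_apparent_umol_l = 250.0
km_umol_l = 88.0
vmax = 1.30
vmax_unit = "nmol/min/mg"
localization = "cytosolic"
enzyme_content_pmol_mg = 75.0
product = "reduced haloperidol"

[[pathway]]
enzyme = "UGT1A4"
reaction = "O-glucuronidation"
system = "recombinant"
km_apparent_umol_l = 64.0
km_umol_l = 22.4
vmax = 600.0
vmax_unit = "pmol/min/mg"
isef = 0.16
localization = "microsomal"
enzyme_content_pmol_mg = 33.0
product = "sink"

[[pathway]]
enzyme = "UGT1A9"
reaction = "O-glucuronidation"
system = "recombinant"
km_apparent_umol_l = 174.0
km_umol_l = 61.0
vmax = 2300.0
vmax_unit = "pmol/min/mg"
isef = 0.06
localization = "microsomal"
enzyme_content_pmol_mg = 22.7
product = "sink"

[[pathway]]
enzyme = "UGT2B7"
reaction = "O-glucuronidation"
system = "recombinant"
km_apparent_umol_l = 45.0
km_umol_l = 16.0
vmax = 1000.0
vmax_unit = "pmol/min/mg"
isef = 0.05
localization = "microsomal"
enzyme_content_pmol_mg = 69.4
product = "sink"

[[pathway]]
# N-glucuronidation Km is loaded exactly as tabulated (64), without the
# fu,inc correction; a loader flag can apply the correction instead.
enzyme = "UGT1A4"
reaction = "N-glucuronidation"
system = "recombinant"
km_umol_l = 64.0
vmax = 440.0
vmax_unit = "pmol/min/mg"
isef = 0.16
localization = "microsomal"
enzyme_content_pmol_mg = 33.0
product = "sink"
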