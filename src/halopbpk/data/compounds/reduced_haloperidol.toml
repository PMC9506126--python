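# Reduced haloperidol (RHAL), the carbonyl-reduction metabolite.
# Back-oxidation to haloperidol is CYP3A4-mediated; the remaining hepatic
# elimination is lumped into a linear plasma-driven hepatic clearance.

name = "reduced haloperidol"
molecular_weight = 378.0
effective_molecular_weight = 339.0
log_p = 3.52
pka = 8.66
ionization = "monoprotic-base"
water_solubility_mg_ml = 0.0131
fraction_unbound = 0.244
intestinal_permeability_cm_min = 2.08e-4
gfr_fraction = 0.0                # no renal route tabulated for the metabolite
fu_incubation = 1.0
blood_plasma_ratio = 1.0
additional_hepatic_clearance_ml_min_kg = 5.0

[[pathway]]
enzyme = "CYP3A4"
reaction = "back-oxidation to haloperidol"
system = "HLM"
km_umol_l = 46.0
vmax = 98.0
vmax_unit = "pmol/min/mg"
localization = "microsomal"
product = "haloperidol"
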