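# Methods

## Scope and model structure

`halopbpk` is a whole-body physiologically based pharmacokinetic (PBPK)
model of haloperidol and its major metabolite, reduced haloperidol (RHAL),
for healthy/psychotic adults, tuberculosis (TB) patients, and rifampicin
co-treatment. The body is represented as fourteen perfusion-limited organ
compartments (adipose, bone, brain, gut, stomach, spleen, pancreas, heart,
kidney, liver, lung, muscle, skin, and a residual "rest" compartment)
connected by arterial and venous blood pools; the lung sits in series and
carries total cardiac output, and the splanchnic organs drain into the
liver through the portal vein. For each organ

dA_T/dt = Q_T · (C_ab − C_T · (B:P)/Kp_T),

with amounts integrated in µmol and concentrations reported as venous
plasma ng/mL. Intravenous boluses are administered as 1-minute zero-order
infusions into venous blood to avoid discontinuity artifacts.

At haloperidol's lipophilicity the permeability-limited and
perfusion-limited distribution solutions converge, so distribution is
perfusion-limited throughout; the spec hook for a permeability-limited
variant is a deliberate non-feature of this release.

## Tissue partitioning

Tissue:plasma coefficients follow the Rodgers–Rowland scheme for
moderate-to-strong monoprotic bases: ionization at intracellular pH 7.0
(erythrocyte 7.22) versus plasma pH 7.4, neutral-lipid/phospholipid
partitioning from logP (vegetable-oil scale for adipose,
logP_vow = 1.115·logP − 1.35), and an acidic-phospholipid association
constant back-calculated from blood-cell partitioning. The measured
blood:plasma ratio of haloperidol is not available in the model's sources,
so the configured constant 1.0 is used (`blood_plasma_ratio` in the
compound files). Tissue-composition constants are the published
Rodgers–Rowland tables, shipped as package data with citations
(`data/reference/tissue_composition.csv`).

## Enzyme kinetics and IVIVE

Hepatic elimination is a sum of Michaelis–Menten pathways driven by the
unbound liver water concentration Cu = fu · C_liver/Kp_liver:

v = Vmax_eff · Cu / (Km + Cu),
Vmax_eff = Vmax[µmol/min/mg] · (MPPGL or CPPGL) · liver weight
           · pathway activity multiplier · global metabolic scale
           · induction fold (CYP3A4 only).

All printed Vmax values are converted once, at load, to µmol/min per mg
protein; apparent Km values measured in vitro are corrected for
non-specific incubation binding (Km · fu,inc, fu,inc = 0.35);
recombinant-enzyme rates are scaled to the microsomal system with the
published intersystem extrapolation factors (UGT1A4 0.16, UGT1A9 0.06,
UGT2B7 0.05). Microsomal pathways scale with MPPGL = 40 mg/g liver (the
literature standard; configurable), the cytosolic CBR1 pathway with
CPPGL = 75.4 mg/g as tabulated. The N-glucuronidation Km is loaded exactly
as tabulated (64 µmol/L, no fu,inc correction) because the source table
lists the input equal to the reported value; `correct_all_km=True` applies
the correction instead.

CBR1 converts haloperidol to RHAL mole-for-mole into the metabolite's
liver compartment; RHAL back-oxidizes to haloperidol through CYP3A4
(Km 46 µmol/L, Vmax 98 pmol/min/mg), so parent–metabolite cycling
conserves haloperidol-equivalent moles. RHAL's remaining hepatic
elimination is a lumped linear clearance of 5 mL/min/kg applied to the
liver-outflow plasma concentration ("plasma clearance" reading of the
estimated value; an intrinsic-clearance variant would be a one-line
change and is documented as an open alternative).

Renal elimination is filtration of unbound drug:
CL_R = GFR fraction · GFR · fu, with GFR fraction = 1.0. The tabulated
"GFR fraction 1" is read as the factor 1.0 (not 0.01): with fu = 0.085 and
GFR ≈ 110 mL/min this yields ≈1% of an IV dose excreted unchanged, which
matches the known mass fraction, whereas 0.01 would yield 0.01%.

### The single metabolic calibration

The in-vivo enzyme abundances behind the in-vitro rates are not available
to this implementation, so one global scaling factor multiplies every
pathway's Vmax_eff. It is fixed once by root-finding so that the
mean-individual NCA clearance of the 0.125 mg/kg IV study equals the
observed 11.1 mL/min/kg, then frozen in `data/defaults.toml`
(value 3.278863) and reused unchanged by every scenario, route, and
population. `halopbpk calibrate` recomputes it.

A consequence documented here deliberately: with the tabulated in-vitro
inputs and this IVIVE scheme, carbonyl reduction carries ≈46% and the
UGTs ≈18% of hepatic intrinsic clearance, whereas in-vivo disposition
studies attribute >50% of haloperidol elimination to glucuronidation. The
global factor cannot change pathway shares, and re-weighting individual
pathways would introduce undocumented degrees of freedom, so the model
keeps the printed inputs and the corresponding acceptance check on the
glucuronidation share fails honestly. Predictions of total exposure are
unaffected (total clearance is calibrated); predictions that depend on the
metabolic split (e.g. RHAL formation fraction) inherit this uncertainty.

## Oral absorption

A compartmental gastro-intestinal model: stomach (gastric-emptying
half-life 15 min), seven small-intestinal segments (total transit 3.3 h,
first-order), and a terminal colon sink (unabsorbed drug). Each segment
absorbs dissolved drug into the portal inflow at
ka = P_int · (SA/V) · area multiplier, with P_int the specific intestinal
permeability (3.09×10⁻⁴ cm/min for haloperidol), SA/V = 1.6 cm⁻¹ the
smooth-tube geometry, and an area multiplier of 30 for mucosal
amplification (folds + villi; chosen from anatomical amplification factors
before any comparison with data, giving fa ≈ 0.9 for haloperidol).
Dissolution is first-order (5 h⁻¹) toward a pH-dependent solubility,
Henderson–Hasselbalch scaling of the aqueous solubility for a monoprotic
base (stomach pH 2.0, small intestine pH 6.0→7.4, amplification capped at
1000× to avoid non-physical salt-free supersaturation); a
`fast_dissolution` toggle bypasses dissolution. Absorbed drug passes
through the liver before reaching the systemic circulation (first-pass).
Gut-wall CYP3A4 is off: no intestinal expression inputs are available, and
its systemic effect is absorbed by the calibrated global factor.

## Physiology and populations

Reference adult organ volumes and regional flow fractions are embedded
from standard reference-human compilations (sources cited in
`data/reference/organs.csv`; cardiac output 5.6 L/min, GFR 110 mL/min,
hematocrit 0.45, blood 5.2 L). Volumes scale linearly with body weight,
flows and GFR with weight^0.75; sex and age are carried as metadata only
(no ontogeny). Virtual populations draw weight and age uniformly (or
truncated-normally) over the study ranges and per-enzyme activity
multipliers log-normally with median 1 and CV 0.45, reflecting the up to
10-fold inter-individual variability reported for these enzymes; CV and
seed are explicit arguments and populations are exactly reproducible.

The TB modification multiplies the plasma binding-protein level by a
scale factor (default 0.8, a moderate-hypoalbuminaemia assumption; no
published value is available for this modification), giving
fu' = fu/(fu + scale·(1−fu)). The adjusted fu feeds both partitioning
(Kp = fu'·Kpu) and clearance. Organ flows are left unchanged in TB.

## Rifampicin DDI

Steady-state rifampicin 600 mg is a static fold increase of every CYP3A4
Vmax_eff (parent oxidations and RHAL back-oxidation alike). The fold is
the model's second and last calibrated constant: root-found so the
simulated induced/control AUC ratio on the 5 mg IV TB scenario equals the
reported steady-state ratio 0.60, frozen at 5.9762 in
`data/defaults.toml`. Onset/offset kinetics, rifampicin PK, and CYP3A4
inhibition are out of scope. The dose-adjustment scan simulates the
control arm and induced arms at base dose × (1 + 50/75/100%) and ranks
the arm closest to control exposure.

## Non-compartmental analysis

AUC by linear-up/log-down trapezoid (configurable to plain linear); λz by
unweighted log-linear least squares on the last 4 positive samples
(configurable); AUC_∞ = AUC_0–t + C_last/λz; CL = dose/AUC_∞ in mL/min/kg;
t½ = ln2/λz. A non-decaying tail raises a diagnostic λz error.

### Observed sampling windows

The source studies' sampling schedules are not tabulated, yet an IV-bolus
"Cmax" is meaningless without one (the model's plasma concentration at
the end of the loading minute is 10–50× any reported Cmax). Each
scenario therefore carries a reconstructed first-sample time, fixed a
priori from the apparent volume Dose/Cmax_obs of its own study (≈43 L ⇒
minutes after dosing; ≈330 L ⇒ ≥0.5 h, i.e. post-distribution), stored in
`data/tables/scenario_settings.csv`, and never adjusted afterwards.
Simulated NCA parameters are computed on the profile restricted to that
window, mirroring how the published observed values were derived from
digitized curves. All scenarios simulate 48 h at 12 points/h.

## Evaluation statistics

Ratio = predicted/observed; PE% = |predicted − observed|/observed × 100
(the published tables print magnitudes; a signed flag exists); RMSE =
√(mean (observed − predicted)²); fold error = max(ratio, 1/ratio) with the
two-fold acceptance rule. MFE defaults to the arithmetic mean of
per-study ratios — the convention that reproduces every published footer —
with the literal quotient-of-means form available as a mode flag; the two
coincide when all observed values are equal. Visual-predictive-check
bands are pointwise 5th/95th percentiles over ≥10 profiles on a common
grid, with observed-point coverage reported.

## Synthetic observed data

Real concentration–time curves from the source studies are not shipped
(figure digitization is unreliable); the generator emulates their
statistical structure instead: sparse samples of a bi-exponential decline
with multiplicative log-normal noise (σ = √ln(1+CV²)) and an LLOQ cutoff.
This supports NCA bias/precision experiments and VPC coverage checks with
analytic truths. What it does not emulate: real absorption-phase shapes,
correlated residuals, assay-specific error, or between-study population
differences — so passing synthetic-recovery tests shows the analysis
pipeline is correct, not that the PBPK predictions match any particular
clinical curve; the latter is checked against the published aggregate PK
tables.

## Numerical choices

LSODA (stiff-capable) with rtol 1e-8, atol 1e-12 by default; integration
is segmented at dose-event boundaries with output on a 12 points/h grid.
Intracellular pH 7.0, plasma 7.4, erythrocyte 7.22; liver density 1 g/mL.
Calibration root-finds use Brent's method (scale bracket 0.2–50, fold
bracket 1–50, xtol 1e-3–1e-4). Dissolution saturation uses a hard clip at
zero (non-smooth but benign for LSODA at these tolerances). Mass balance
closes to better than 0.1% in all tested scenarios.

## Known limitations

* The metabolic pathway split disagrees with in-vivo disposition
  literature (see IVIVE section); total exposure is calibrated, the split
  is as the in-vitro inputs imply.
* A single frozen parameterization cannot be within two-fold of every
  published study aggregate because the aggregates themselves span >4-fold
  after dose normalization (e.g. oral dose-normalized AUC 629 vs 3450
  ng·h/mL per mg/kg across studies); the package reports each comparison
  honestly instead of tailoring per study.
* Terminal half-life (~9 h) is at the short end of reported values
  (~10–15 h), consistent with a steady-state volume of ≈4 L/kg from the
  partitioning scheme versus larger literature estimates.
* No pediatric/geriatric ontogeny, pregnancy, renal/hepatic impairment
  (beyond TB protein scaling), intramuscular/intranasal routes,
  enterohepatic recirculation, brain receptor occupancy, or downstream
  kinetics of the terminal oxidative metabolites.
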