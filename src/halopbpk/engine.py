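"""Whole-body PBPK ODE system: assembly, integration, mass balance.

Structure
---------
Fourteen perfusion-limited organs linked by arterial/venous blood, the lung
in series carrying total cardiac output, and the splanchnic organs (gut,
stomach, spleen, pancreas) draining into the liver via the portal vein.
Orally dosed drug moves through a compartmental gastro-intestinal tract
(stomach + 7 small-intestinal segments + colon sink) with first-order
transit, pH-dependent dissolution, and passive segmental absorption into
the portal inflow (first pass through the liver).

Each compound's hepatic metabolism is a sum of Michaelis-Menten pathways
driven by the unbound liver water concentration, with

    Vmax_eff = Vmax[umol/min/mg] * (MPPGL | CPPGL) * liver weight
               * pathway activity multiplier * global metabolic scale
               * induction fold (CYP3A4 pathways only)

Pathway products that name another simulated compound transfer molar
amounts into that compound's liver compartment (parent <-> metabolite
cycling is supported); other products go to terminal sinks.  Renal
elimination is filtration of unbound drug (gfr_fraction * GFR * fu) and a
compound may carry an extra linear plasma-driven hepatic clearance.

Amounts are integrated in umol; concentrations are reported as venous
plasma ng/mL.  IV boluses are administered as 1-minute zero-order
infusions into venous blood to avoid discontinuity artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .compounds import SINK, CompoundModel
from .errors import ConfigurationError, SolverError, ValidationError
from .partition import compute_partition_coefficients
from .physiology import Physiology, apply_plasma_protein_scaling

__all__ = [
    "DoseRegimen",
    "SimulationSpec",
    "ConcentrationTimeProfile",
    "SimulationResult",
    "build_ode_system",
    "simulate",
    "mass_balance_report",
    "simulate_one_compartment",
]

ORGAN_ORDER = (
    "adipose",
    "bone",
    "brain",
    "gut",
    "stomach",
    "spleen",
    "pancreas",
    "heart",
    "kidney",
    "liver",
    "lung",
    "muscle",
    "skin",
    "rest",
)
_LIVER = ORGAN_ORDER.index("liver")
_LUNG = ORGAN_ORDER.index("lung")
_KIDNEY = ORGAN_ORDER.index("kidney")

# Gastro-intestinal constants
GASTRIC_EMPTYING_HALFLIFE_H = 0.25
N_SI_SEGMENTS = 7
SI_TRANSIT_TOTAL_H = 3.3
SI_SEGMENT_PH = (6.0, 6.2, 6.4, 6.6, 6.9, 7.2, 7.4)
STOMACH_PH = 2.0
SEGMENT_FLUID_L = 0.03
STOMACH_FLUID_L = 0.25
SURFACE_TO_VOLUME_CM = 1.6  # smooth-tube 2/r at r = 1.25 cm
DEFAULT_AREA_MULTIPLIER = 30.0  # mucosal amplification (folds + villi)
DISSOLUTION_RATE_H = 5.0
_HH_CAP = 1000.0  # cap on the Henderson-Hasselbalch solubility amplification

IV_BOLUS_DURATION_H = 1.0 / 60.0


@dataclass(frozen=True)
class DoseRegimen:
    """One administration: route 'iv-bolus' | 'iv-infusion' | 'oral',
    amount in mg (absolute, or mg/kg with per_kg=True)."""

    route: str
    amount: float
    per_kg: bool = False
    start: float = 0.0
    infusion_duration: float | None = None

    def __post_init__(self) -> None:
        if self.route not in ("iv-bolus", "iv-infusion", "oral"):
            raise ValidationError(f"unknown route {self.route!r}")
        if self.amount <= 0:
            raise ValidationError("dose amount must be > 0")
        if self.route == "iv-infusion" and not (
            self.infusion_duration and self.infusion_duration > 0
        ):
            raise ValidationError("iv-infusion requires infusion_duration > 0")

    def amount_mg(self, body_weight: float) -> float:
        return self.amount * body_weight if self.per_kg else self.amount


@dataclass
class ConcentrationTimeProfile:
    """Venous plasma concentration (ng/mL) on a time grid (h)."""

    compound: str
    times: np.ndarray
    concentrations: np.ndarray
    label: str = "mean"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValidationError("times and concentrations differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.concentrations < -1e-9):
            raise ValidationError("negative concentrations")
        self.concentrations = np.clip(self.concentrations, 0.0, None)

    def window(self, t_start: float, t_end: float | None = None) -> "ConcentrationTimeProfile":
        """Restrict to the observed sampling window [t_start, t_end]."""
        mask = self.times >= t_start - 1e-12
        if t_end is not None:
            mask &= self.times <= t_end + 1e-12
        return ConcentrationTimeProfile(
            self.compound, self.times[mask], self.concentrations[mask], self.label
        )


@dataclass
class SimulationSpec:
    """Everything needed to run one simulation."""

    compounds: list[CompoundModel]
    physiology: Physiology | None = None
    population: list[Physiology] | None = None
    dose_events: list[DoseRegimen] = field(default_factory=list)
    duration: float = 48.0  # h
    output_points_per_hour: int = 12
    global_metabolic_scale: float = 1.0
    cyp3a4_induction_fold: float = 1.0
    area_multiplier: float = DEFAULT_AREA_MULTIPLIER
    fast_dissolution: bool = False
    rtol: float = 1e-8
    atol: float = 1e-12
    label: str = "scenario"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("duration must be > 0")
        if not 1 <= len(self.compounds) <= 2:
            raise ValidationError("1 or 2 compounds supported (parent, metabolite)")
        if self.physiology is None and not self.population:
            raise ValidationError("physiology or population required")
        if self.cyp3a4_induction_fold < 1:
            raise ValidationError("induction fold must be >= 1")
        names = {c.name for c in self.compounds}
        for c in self.compounds:
            for p in c.pathways:
                if p.product != SINK and p.product not in names:
                    raise ConfigurationError(
                        f"pathway {p.key} of {c.name} produces {p.product!r}, "
                        "which is neither a simulated compound nor 'sink'"
                    )
        for d in self.dose_events:
            if d.start >= self.duration:
                raise ValidationError("dose event beyond simulation duration")


class _CompoundLayout:
    """Index bookkeeping and precomputed rate constants for one compound."""

    def __init__(
        self,
        compound: CompoundModel,
        physiology: Physiology,
        spec: SimulationSpec,
        offset: int,
        compound_index: dict[str, int],
    ):
        self.compound = compound
        self.fu = apply_plasma_protein_scaling(
            compound.fraction_unbound, physiology.plasma_protein_scale
        )
        self.bp = compound.blood_plasma_ratio
        self.mw = compound.molecular_weight
        kp = compute_partition_coefficients(compound, physiology, fu_override=self.fu)
        self.kp = np.array([kp[n] for n in ORGAN_ORDER])
        self.volumes = np.array([physiology.organs[n].volume for n in ORGAN_ORDER])
        self.organs = slice(offset, offset + len(ORGAN_ORDER))
        self.i_art = offset + len(ORGAN_ORDER)
        self.i_ven = self.i_art + 1
        self.cl_renal = (
            compound.gfr_fraction * physiology.gfr * 0.06 * self.fu
        )  # L/h, driven by arterial plasma
        self.cl_additional = (
            compound.additional_hepatic_clearance * physiology.body_weight * 0.06
        )  # L/h, driven by liver outflow plasma
        # pathways: (vmax_eff umol/h, km, product compound idx or -1)
        self.pathways: list[tuple[float, float, int]] = []
        for p in compound.pathways:
            protein = (
                physiology.cppgl if p.localization == "cytosolic" else physiology.mppgl
            )
            vmax_eff = (
                p.vmax_umol_min_mg
                * 60.0
                * protein
                * physiology.liver_weight
                * physiology.multiplier(p.enzyme)
                * spec.global_metabolic_scale
            )
            if p.is_cyp3a4:
                vmax_eff *= spec.cyp3a4_induction_fold
            target = compound_index.get(p.product, -1)
            self.pathways.append((vmax_eff, p.km, target))
        self.n_pathways = len(self.pathways)


class _System:
    """Assembled right-hand side + dose schedule for one individual."""

    def __init__(self, spec: SimulationSpec, physiology: Physiology):
        self.spec = spec
        self.phys = physiology
        names = [c.name for c in spec.compounds]
        cindex = {n: i for i, n in enumerate(names)}
        self.layouts: list[_CompoundLayout] = []
        off = 0
        for c in spec.compounds:
            lay = _CompoundLayout(c, physiology, spec, off, cindex)
            self.layouts.append(lay)
            off = lay.i_ven + 1
        # lumen block (parent only)
        self.has_oral = any(d.route == "oral" for d in spec.dose_events)
        self.i_lumen = off
        # stomach solid, stomach dissolved, 7x solid, 7x dissolved, colon
        self.n_lumen = 2 + 2 * N_SI_SEGMENTS + 1
        off += self.n_lumen
        # accumulators: per compound renal, additional, pathways...
        self.acc_index: list[dict[str, int]] = []
        for lay in self.layouts:
            d = {"renal": off, "additional_hepatic": off + 1}
            off += 2
            for p in lay.compound.pathways:
                d[p.key] = off
                off += 1
            self.acc_index.append(d)
        self.n_states = off
        self._prepare_flows()
        self._prepare_gi()
        self._prepare_schedule()

    # -- assembly ---------------------------------------------------------
    def _prepare_flows(self) -> None:
        ph = self.phys
        self.q = np.array([ph.organs[n].blood_flow for n in ORGAN_ORDER])
        self.portal_mask = np.array(
            [ph.organs[n].portal for n in ORGAN_ORDER], dtype=bool
        )
        self.co = ph.cardiac_output
        self.q_liver_in = ph.liver_total_flow
        # systemic organs returning directly to the venous pool
        self.systemic_mask = ~self.portal_mask.copy()
        self.systemic_mask[_LIVER] = False
        self.systemic_mask[_LUNG] = False
        self.v_art = ph.arterial_volume
        self.v_ven = ph.venous_volume

    def _prepare_gi(self) -> None:
        parent = self.spec.compounds[0]
        self.k_ge = math.log(2.0) / GASTRIC_EMPTYING_HALFLIFE_H
        self.k_transit = N_SI_SEGMENTS / SI_TRANSIT_TOTAL_H
        perm_cm_h = parent.intestinal_permeability * 60.0
        self.ka_seg = (
            perm_cm_h * SURFACE_TO_VOLUME_CM * self.spec.area_multiplier
        )  # 1/h, same for all SI segments
        s0 = parent.water_solubility  # mg/mL == g/L
        pka = parent.pka

        def sol_umol_l(ph_seg: float) -> float:
            amp = min(1.0 + 10.0 ** (pka - ph_seg), _HH_CAP)
            return s0 * amp / parent.molecular_weight * 1e6

        self.sol_stomach = sol_umol_l(STOMACH_PH)
        self.sol_si = np.array([sol_umol_l(p) for p in SI_SEGMENT_PH])

    def _prepare_schedule(self) -> None:
        """Split [0, duration] at dose boundaries; per segment a constant
        IV infusion rate (umol/h) and instantaneous oral additions at the
        segment start."""
        bw = self.phys.body_weight
        mw = self.layouts[0].mw
        events: list[tuple[float, float, float]] = []  # start, end, rate
        boluses: list[tuple[float, float]] = []  # time, umol into stomach
        for d in self.spec.dose_events:
            umol = d.amount_mg(bw) / mw * 1e3  # mg -> umol
            if d.route == "oral":
                boluses.append((d.start, umol))
            else:
                dur = (
                    IV_BOLUS_DURATION_H
                    if d.route == "iv-bolus"
                    else d.infusion_duration
                )
                end = min(d.start + dur, self.spec.duration)
                events.append((d.start, end, umol / dur))
        cuts = {0.0, self.spec.duration}
        cuts.update(t for ev in events for t in (ev[0], ev[1]))
        cuts.update(t for t, _ in boluses)
        self.boundaries = sorted(c for c in cuts if 0.0 <= c <= self.spec.duration)
        self.iv_events = events
        self.oral_boluses = boluses

    # -- right-hand side --------------------------------------------------
    def rhs(self, t: float, y: np.ndarray, iv_rate: float) -> np.ndarray:
        dy = np.zeros_like(y)
        spec = self.spec
        formation = np.zeros(len(self.layouts))  # umol/h into each liver
        for ci, lay in enumerate(self.layouts):
            a = y[lay.organs]
            c_t = a / lay.volumes
            c_out = c_t * lay.bp / lay.kp  # blood conc leaving each organ
            c_ab = y[lay.i_art] / self.v_art
            c_vb = y[lay.i_ven] / self.v_ven
            d_org = self.q * (c_ab - c_out)
            # lung in series
            d_org[_LUNG] = self.co * (c_vb - c_out[_LUNG])
            # liver: hepatic artery + portal inflow, single outflow
            portal_in = float(np.sum(self.q[self.portal_mask] * c_out[self.portal_mask]))
            d_org[_LIVER] = (
                self.q[_LIVER] * c_ab
                + portal_in
                - self.q_liver_in * c_out[_LIVER]
            )
            # renal filtration of unbound drug, from the kidney
            renal = lay.cl_renal * c_ab / lay.bp
            d_org[_KIDNEY] -= renal
            dy[self.acc_index[ci]["renal"]] += renal
            # hepatic metabolism on unbound liver water
            cu = lay.fu * c_t[_LIVER] / lay.kp[_LIVER]
            for (vmax_eff, km, target), p in zip(lay.pathways, lay.compound.pathways):
                v = vmax_eff * cu / (km + cu)
                d_org[_LIVER] -= v
                dy[self.acc_index[ci][p.key]] += v
                if target >= 0:
                    formation[target] += v
            # lumped linear hepatic clearance (plasma-driven)
            if lay.cl_additional > 0:
                v_add = lay.cl_additional * c_t[_LIVER] / lay.kp[_LIVER]
                d_org[_LIVER] -= v_add
                dy[self.acc_index[ci]["additional_hepatic"]] += v_add
            dy[lay.organs] = d_org
            sys_in = float(
                np.sum(self.q[self.systemic_mask] * c_out[self.systemic_mask])
            )
            dy[lay.i_ven] = (
                sys_in + self.q_liver_in * c_out[_LIVER] - self.co * c_vb
            )
            dy[lay.i_art] = self.co * (c_out[_LUNG] - c_ab)
        if iv_rate:
            dy[self.layouts[0].i_ven] += iv_rate
        for ci, f in enumerate(formation):
            if f:
                dy[self.layouts[ci].organs.start + _LIVER] += f
        if self.has_oral:
            self._lumen_rhs(y, dy)
        return dy

    def _lumen_rhs(self, y: np.ndarray, dy: np.ndarray) -> None:
        i0 = self.i_lumen
        st_solid, st_diss = y[i0], y[i0 + 1]
        si_solid = y[i0 + 2 : i0 + 2 + N_SI_SEGMENTS]
        si_diss = y[i0 + 2 + N_SI_SEGMENTS : i0 + 2 + 2 * N_SI_SEGMENTS]
        k_ge, k_t = self.k_ge, self.k_transit
        # stomach
        if self.spec.fast_dissolution:
            diss_st = DISSOLUTION_RATE_H * 100.0 * st_solid
        else:
            sat = max(0.0, 1.0 - st_diss / STOMACH_FLUID_L / self.sol_stomach)
            diss_st = DISSOLUTION_RATE_H * st_solid * sat
        dy[i0] = -k_ge * st_solid - diss_st
        dy[i0 + 1] = -k_ge * st_diss + diss_st
        # small intestine
        in_solid, in_diss = k_ge * st_solid, k_ge * st_diss
        absorbed = 0.0
        for s in range(N_SI_SEGMENTS):
            if self.spec.fast_dissolution:
                diss = DISSOLUTION_RATE_H * 100.0 * si_solid[s]
            else:
                sat = max(
                    0.0, 1.0 - si_diss[s] / SEGMENT_FLUID_L / self.sol_si[s]
                )
                diss = DISSOLUTION_RATE_H * si_solid[s] * sat
            ab = self.ka_seg * si_diss[s]
            absorbed += ab
            dy[i0 + 2 + s] = in_solid - k_t * si_solid[s] - diss
            dy[i0 + 2 + N_SI_SEGMENTS + s] = in_diss - k_t * si_diss[s] + diss - ab
            in_solid = k_t * si_solid[s]
            in_diss = k_t * si_diss[s]
        dy[i0 + 2 + 2 * N_SI_SEGMENTS] = in_solid + in_diss  # colon sink
        # absorbed drug enters the liver with the portal inflow
        dy[self.layouts[0].organs.start + _LIVER] += absorbed

    def conserved_total(self, y: np.ndarray) -> np.ndarray:
        """Molar amount accounted for at a state (vectorized over the
        trailing axis): body burden of every compound + GI lumen + terminal
        sinks.  Accumulators of pathways that transfer to the partner
        compound are excluded (their product is already counted as body
        burden), so this total must equal the cumulative administered dose."""
        total = np.zeros_like(np.asarray(y[0]))
        for ci, lay in enumerate(self.layouts):
            total = total + y[lay.organs].sum(axis=0) + y[lay.i_art] + y[lay.i_ven]
            acc = self.acc_index[ci]
            total = total + y[acc["renal"]] + y[acc["additional_hepatic"]]
            for p in lay.compound.pathways:
                if p.product == SINK:
                    total = total + y[acc[p.key]]
        if self.has_oral:
            total = total + y[self.i_lumen : self.i_lumen + self.n_lumen].sum(axis=0)
        return total

    # -- integration ------------------------------------------------------
    def integrate(self) -> tuple[np.ndarray, np.ndarray]:
        spec = self.spec
        n_pts = max(2, int(round(spec.duration * spec.output_points_per_hour)) + 1)
        grid = np.linspace(0.0, spec.duration, n_pts)
        y = np.zeros(self.n_states)
        ts: list[np.ndarray] = []
        ys: list[np.ndarray] = []
        for t0, t1 in zip(self.boundaries[:-1], self.boundaries[1:]):
            for t_dose, umol in self.oral_boluses:
                if abs(t_dose - t0) < 1e-12:
                    if spec.fast_dissolution:
                        y[self.i_lumen + 1] += umol
                    else:
                        y[self.i_lumen] += umol
            rate = sum(r for (s, e, r) in self.iv_events if s <= t0 < e)
            t_eval = grid[(grid >= t0 - 1e-12) & (grid <= t1 + 1e-12)]
            t_eval = np.unique(np.concatenate([[t0], t_eval, [t1]]))
            sol = solve_ivp(
                self.rhs,
                (t0, t1),
                y,
                method="LSODA",
                t_eval=t_eval,
                args=(rate,),
                rtol=spec.rtol,
                atol=spec.atol,
            )
            if not sol.success:
                raise SolverError(
                    f"integration failed in scenario {spec.label!r} "
                    f"on [{t0}, {t1}]: {sol.message}"
                )
            ts.append(sol.t)
            ys.append(sol.y)
            y = sol.y[:, -1].copy()
        t_all = np.concatenate(ts)
        y_all = np.concatenate(ys, axis=1)
        keep = np.concatenate([[True], np.diff(t_all) > 1e-12])
        return t_all[keep], y_all[:, keep]


@dataclass
class SimulationResult:
    spec: SimulationSpec
    times: np.ndarray
    profiles: list[ConcentrationTimeProfile]
    final_state: np.ndarray | None = None
    system: object | None = None
    individual_profiles: list[ConcentrationTimeProfile] = field(default_factory=list)

    def profile(self, compound: str, label: str = "mean") -> ConcentrationTimeProfile:
        for p in self.profiles:
            if p.compound == compound and p.label == label:
                return p
        raise KeyError((compound, label))


def build_ode_system(spec: SimulationSpec, physiology: Physiology | None = None):
    """Assemble the ODE system for one individual (exposed for tests and
    diagnostics); returns an object with .rhs, .boundaries, .integrate."""
    return _System(spec, physiology or spec.physiology)


def _simulate_individual(spec: SimulationSpec, phys: Physiology):
    system = _System(spec, phys)
    t, y = system.integrate()
    profiles = []
    for lay in system.layouts:
        conc = (y[lay.i_ven] / system.v_ven) / lay.bp * lay.mw  # umol/L -> ng/mL
        profiles.append(
            ConcentrationTimeProfile(lay.compound.name, t, conc, phys.label)
        )
    return system, t, y, profiles


def simulate(spec: SimulationSpec, percentiles=(5.0, 95.0)) -> SimulationResult:
    """Run the simulation.

    Mean-individual mode returns one profile per compound.  Population
    mode returns, per compound, the per-individual profiles plus pointwise
    mean and percentile bands.
    """
    if spec.population:
        all_profiles: list[ConcentrationTimeProfile] = []
        per_comp: dict[str, list[np.ndarray]] = {c.name: [] for c in spec.compounds}
        times = None
        for phys in spec.population:
            _, t, _, profs = _simulate_individual(spec, phys)
            times = t
            for p in profs:
                per_comp[p.compound].append(p.concentrations)
                all_profiles.append(p)
        summary = []
        for cname, stack in per_comp.items():
            arr = np.vstack(stack)
            summary.append(
                ConcentrationTimeProfile(cname, times, arr.mean(axis=0), "mean")
            )
            for q in percentiles:
                summary.append(
                    ConcentrationTimeProfile(
                        cname, times, np.percentile(arr, q, axis=0), f"p{q:g}"
                    )
                )
        return SimulationResult(
            spec, times, summary, individual_profiles=all_profiles
        )
    system, t, y, profiles = _simulate_individual(spec, spec.physiology)
    return SimulationResult(spec, t, profiles, final_state=y[:, -1], system=system)


def mass_balance_report(result: SimulationResult) -> dict:
    """Disposition fractions at the end of a mean-individual simulation.

    Per compound: fraction of total input (dose + amount formed from the
    partner compound) that is in the body, still in the GI lumen, lost
    unabsorbed (colon), eliminated renally, via each pathway, or via the
    lumped hepatic clearance.  Fractions sum to 1 within 0.1%.
    """
    if result.final_state is None or result.system is None:
        raise ValidationError("mass balance needs a mean-individual simulation")
    system: _System = result.system
    y = result.final_state
    bw = system.phys.body_weight
    report: dict[str, dict] = {}
    for ci, lay in enumerate(system.layouts):
        dose_umol = sum(
            d.amount_mg(bw) / lay.mw * 1e3
            for d in result.spec.dose_events
        ) if ci == 0 else 0.0
        formed = sum(
            y[system.acc_index[cj][p.key]]
            for cj, other in enumerate(system.layouts)
            for p in other.compound.pathways
            if p.product == lay.compound.name
        )
        total_in = dose_umol + formed
        body = float(np.sum(y[lay.organs]) + y[lay.i_art] + y[lay.i_ven])
        lumen = colon = 0.0
        if ci == 0 and system.has_oral:
            i0 = system.i_lumen
            colon = float(y[i0 + 2 + 2 * N_SI_SEGMENTS])
            lumen = float(np.sum(y[i0 : i0 + 2 + 2 * N_SI_SEGMENTS]))
        entry = {
            "input_umol": total_in,
            "dose_umol": dose_umol,
            "formed_umol": formed,
            "fraction_in_body": body / total_in if total_in else 0.0,
            "fraction_lumen": lumen / total_in if total_in else 0.0,
            "fraction_unabsorbed": colon / total_in if total_in else 0.0,
            "fraction_renal": y[system.acc_index[ci]["renal"]] / total_in
            if total_in
            else 0.0,
            "fraction_additional_hepatic": y[
                system.acc_index[ci]["additional_hepatic"]
            ]
            / total_in
            if total_in
            else 0.0,
            "pathways": {},
        }
        for p in lay.compound.pathways:
            entry["pathways"][p.key] = (
                y[system.acc_index[ci][p.key]] / total_in if total_in else 0.0
            )
        closure = (
            entry["fraction_in_body"]
            + entry["fraction_lumen"]
            + entry["fraction_unabsorbed"]
            + entry["fraction_renal"]
            + entry["fraction_additional_hepatic"]
            + sum(entry["pathways"].values())
        )
        entry["closure"] = closure
        report[lay.compound.name] = entry
    return report


def simulate_one_compartment(
    dose_mg: float,
    volume_l: float,
    clearance_l_h: float,
    duration_h: float,
    mw: float = 376.0,
    points_per_hour: int = 12,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> ConcentrationTimeProfile:
    """Degenerate engine configuration: a single well-stirred compartment
    with linear clearance, dosed with the same 1-minute pseudo-bolus the
    whole-body model uses.  Used to verify the integrator against the
    closed form C(t) = (Dose/V) exp(-CL t / V)."""
    umol = dose_mg / mw * 1e3
    rate = umol / IV_BOLUS_DURATION_H
    k = clearance_l_h / volume_l

    def rhs(t, y, infusion):
        return [infusion - k * y[0]]

    grid = np.linspace(0.0, duration_h, int(duration_h * points_per_hour) + 1)
    y0 = [0.0]
    segs = [(0.0, IV_BOLUS_DURATION_H, rate), (IV_BOLUS_DURATION_H, duration_h, 0.0)]
    ts, cs = [], []
    for t0, t1, r in segs:
        t_eval = np.unique(
            np.concatenate([[t0], grid[(grid >= t0) & (grid <= t1)], [t1]])
        )
        sol = solve_ivp(
            rhs, (t0, t1), y0, method="LSODA", t_eval=t_eval, args=(r,),
            rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise SolverError("one-compartment reduction failed")
        ts.append(sol.t)
        cs.append(sol.y[0] / volume_l * mw)
        y0 = [sol.y[0, -1]]
    t_all = np.concatenate(ts)
    c_all = np.concatenate(cs)
    keep = np.concatenate([[True], np.diff(t_all) > 1e-12])
    return ConcentrationTimeProfile("one-compartment", t_all[keep], c_all[keep])
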