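"""Tissue-to-plasma partition coefficients (Rodgers-Rowland scheme).

For a moderate-to-strong monoprotic base (pKa >= ~7) the tissue-to-unbound-
plasma coefficient is

    Kpu = f_EW
        + f_IW * (1 + X_IW) / (1 + X_P)
        + Ka_AP * AP_t * X_IW / (1 + X_P)
        + (P * f_NL + (0.3 P + 0.7) * f_NP) / (1 + X_P)

with X = 10^(pKa - pH) the ionized:neutral ratio at intracellular
(pH 7.0), erythrocyte (pH 7.22) and plasma (pH 7.4) pH, P the
octanol:water partition coefficient (vegetable-oil:water for adipose), and
Ka_AP the association constant to acidic phospholipids, back-calculated
from the measured blood:plasma ratio via erythrocyte partitioning.  The
tissue:plasma coefficient is Kp = fu * Kpu.

For weak bases/neutrals (pKa well below plasma pH) the ionization terms
vanish and the same expression reduces to the water + neutral-lipid form.
"""

from __future__ import annotations

from .compounds import CompoundModel
from .errors import ConfigurationError
from .physiology import BLOOD_CELL_COMPOSITION, Physiology, TissueComposition

__all__ = [
    "PH_PLASMA",
    "PH_INTRACELLULAR",
    "PH_BLOOD_CELLS",
    "acidic_phospholipid_association",
    "kpu_base",
    "compute_partition_coefficients",
]

PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0
PH_BLOOD_CELLS = 7.22

# vegetable oil : water lipophilicity for adipose neutral lipid,
# logP_vow = 1.115 logP - 1.35 (Poulin & Theil regression)
_VOW_SLOPE, _VOW_INTERCEPT = 1.115, -1.35


def _ionized_ratio(pka: float, ph: float) -> float:
    return 10.0 ** (pka - ph)


def _lipid_term(p_ow: float, comp: TissueComposition) -> float:
    return p_ow * comp.f_neutral_lipid + (0.3 * p_ow + 0.7) * comp.f_neutral_phospholipid


def acidic_phospholipid_association(compound: CompoundModel, hematocrit: float) -> float:
    """Back-calculate Ka_AP from the blood:plasma ratio via erythrocyte
    partitioning: Kpu_BC = (BP - (1 - Hct)) / (Hct * fu)."""
    bc = BLOOD_CELL_COMPOSITION
    fu = compound.fraction_unbound
    bp = compound.blood_plasma_ratio
    kpu_bc = (bp - (1.0 - hematocrit)) / (hematocrit * fu)
    x_p = _ionized_ratio(compound.pka, PH_PLASMA)
    x_bc = _ionized_ratio(compound.pka, PH_BLOOD_CELLS)
    p_ow = 10.0**compound.log_p
    neutral = bc.f_water_intracellular * (1.0 + x_bc) / (1.0 + x_p) + _lipid_term(
        p_ow, bc
    ) / (1.0 + x_p)
    if x_bc <= 0:
        return 0.0
    ka = (kpu_bc - neutral) * (1.0 + x_p) / (bc.acidic_phospholipid * x_bc)
    return max(ka, 0.0)


def kpu_base(
    compound: CompoundModel,
    comp: TissueComposition,
    ka_ap: float,
    *,
    ph_iw: float = PH_INTRACELLULAR,
    adipose: bool = False,
) -> float:
    """Tissue-to-unbound-plasma coefficient for one tissue."""
    x_p = _ionized_ratio(compound.pka, PH_PLASMA)
    x_iw = _ionized_ratio(compound.pka, ph_iw)
    log_p = compound.log_p
    if adipose:
        log_p = _VOW_SLOPE * compound.log_p + _VOW_INTERCEPT
    p_ow = 10.0**log_p
    return (
        comp.f_water_extracellular
        + comp.f_water_intracellular * (1.0 + x_iw) / (1.0 + x_p)
        + ka_ap * comp.acidic_phospholipid * x_iw / (1.0 + x_p)
        + _lipid_term(p_ow, comp) / (1.0 + x_p)
    )


def compute_partition_coefficients(
    compound: CompoundModel,
    physiology: Physiology,
    *,
    fu_override: float | None = None,
) -> dict[str, float]:
    """Per-organ tissue:plasma partition coefficients Kp = fu * Kpu.

    `fu_override` substitutes a disease-adjusted unbound fraction (the
    association constant is still derived from the healthy blood:plasma
    measurement, which is a drug property).
    """
    if compound.ionization != "monoprotic-base":
        raise ConfigurationError(
            f"only monoprotic bases are supported, got {compound.ionization!r}"
        )
    fu = compound.fraction_unbound if fu_override is None else fu_override
    ka_ap = acidic_phospholipid_association(compound, physiology.hematocrit)
    out: dict[str, float] = {}
    for name, organ in physiology.organs.items():
        if organ.composition is None:
            raise ConfigurationError(f"no tissue composition for organ {name!r}")
        kpu = kpu_base(
            compound, organ.composition, ka_ap, adipose=(name == "adipose")
        )
        out[name] = fu * kpu
    return out


def blood_plasma_ratio(compound: CompoundModel, hematocrit: float) -> float:
    """Blood:plasma concentration ratio used to convert blood-borne flow
    terms to plasma concentrations (config constant on the compound)."""
    return compound.blood_plasma_ratio


def vss_plasma(kp: dict[str, float], physiology: Physiology) -> float:
    """Apparent steady-state volume of distribution referenced to plasma
    (L): V_blood-as-plasma + sum Kp_t * V_t."""
    v_blood = physiology.arterial_volume + physiology.venous_volume
    return v_blood + sum(kp[n] * o.volume for n, o in physiology.organs.items())
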