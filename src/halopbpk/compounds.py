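"""Drug-dependent parameter sets and derived-parameter calculations.

A :class:`CompoundModel` holds the physicochemical and ADME inputs for one
drug; a :class:`MetabolicPathway` holds one saturable hepatic reaction
(enzyme, in-vitro system, Michaelis constant, maximal rate).  The functions
here implement the pre-simulation arithmetic of in-vitro-to-in-vivo
extrapolation:

* binding correction of apparent Km for non-specific incubation binding
  (``Km_corrected = Km_apparent * fu_inc``);
* conversion of per-pmol-CYP rates to per-mg-microsomal-protein rates;
* the cytosolic enzyme reference concentration in whole liver;
* scaling of recombinant-system rates to liver microsomes with an
  intersystem extrapolation factor (ISEF).

All Vmax values are converted once, at load, to a single internal unit
(umol/min per mg protein); the printed values and units are retained for
display and round-tripping.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Optional

from .errors import InvalidParameterError, ValidationError

__all__ = [
    "MetabolicPathway",
    "CompoundModel",
    "correct_km",
    "convert_vmax_per_pmol",
    "cytosolic_reference_concentration",
    "apply_isef",
    "haloperidol_model",
    "reduced_haloperidol_model",
    "load_compound",
]

_VMAX_UNIT_TO_UMOL = {
    "pmol/min/mg": 1e-6,
    "nmol/min/mg": 1e-3,
    "umol/min/mg": 1.0,
}

#: Terminal metabolite pool: the reaction product is not tracked further.
SINK = "sink"


def correct_km(km_apparent: float, fu_incubation: float) -> float:
    """Correct an apparent Michaelis constant for non-specific binding in
    the in-vitro incubation.

    Only the unbound drug in the incubation is available to the enzyme, so
    the operative constant is ``km_apparent * fu_incubation`` (umol/L).
    """
    if km_apparent <= 0:
        raise InvalidParameterError(f"km_apparent must be > 0, got {km_apparent}")
    if not 0 < fu_incubation <= 1:
        raise InvalidParameterError(
            f"fu_incubation must be in (0, 1], got {fu_incubation}"
        )
    return km_apparent * fu_incubation


def convert_vmax_per_pmol(vmax_per_pmol: float, cyp_content: float) -> float:
    """Convert a per-pmol-enzyme rate (pmol/min/pmol CYP) to a
    per-mg-microsomal-protein rate, given the microsomal CYP content
    (pmol/mg protein)."""
    if vmax_per_pmol < 0 or cyp_content < 0:
        raise InvalidParameterError("vmax and CYP content must be non-negative")
    return vmax_per_pmol * cyp_content


def cytosolic_reference_concentration(
    content: float, cppgl: float, *, report: bool = False
) -> float:
    """Reference concentration (umol/L liver) of a cytosolic enzyme.

    ``content`` is pmol per mg cytosolic protein, ``cppgl`` mg cytosolic
    protein per g liver; division by 1000 converts per-gram to per-mL
    assuming unit liver density.  With ``report=True`` the value is rounded
    to 2 significant figures as reported; the exact value is used internally.
    """
    if content < 0 or cppgl < 0:
        raise InvalidParameterError("content and cppgl must be non-negative")
    value = content * cppgl / 1000.0
    if report and value > 0:
        # reported to 2 significant figures, truncating (5.655 -> 5.6)
        ndigits = 1 - int(math.floor(math.log10(abs(value))))
        factor = 10.0**ndigits
        return math.floor(value * factor + 1e-9) / factor
    return value


def apply_isef(vmax_recombinant: float, isef: float) -> float:
    """Scale a recombinant-system Vmax to the liver-microsomal system with
    an intersystem extrapolation factor (ISEF in (0, 1])."""
    if vmax_recombinant < 0:
        raise InvalidParameterError("vmax must be non-negative")
    if not 0 < isef <= 1:
        raise InvalidParameterError(f"isef must be in (0, 1], got {isef}")
    return vmax_recombinant * isef


@dataclass
class MetabolicPathway:
    """One saturable hepatic reaction of a compound."""

    enzyme: str
    reaction: str
    system: str  # "HLM" | "HLC" | "recombinant"
    km: float  # operative (binding-corrected) Km, umol/L
    vmax: float  # as printed, in `vmax_unit`
    vmax_unit: str
    localization: str  # "microsomal" | "cytosolic"
    product: str = SINK
    km_apparent: Optional[float] = None
    isef: Optional[float] = None
    enzyme_content: Optional[float] = None  # pmol per mg protein

    def __post_init__(self) -> None:
        if self.km <= 0:
            raise ValidationError(f"{self.enzyme} {self.reaction}: km must be > 0")
        if self.vmax < 0:
            raise ValidationError(f"{self.enzyme}: vmax must be >= 0")
        if self.km_apparent is not None and self.km > self.km_apparent:
            raise ValidationError(
                f"{self.enzyme} {self.reaction}: corrected Km exceeds apparent Km"
            )
        if self.isef is not None and not 0 < self.isef <= 1:
            raise ValidationError(f"{self.enzyme}: ISEF must be in (0, 1]")
        if self.vmax_unit not in _VMAX_UNIT_TO_UMOL:
            raise ValidationError(f"unknown vmax unit {self.vmax_unit!r}")
        if self.localization not in ("microsomal", "cytosolic"):
            raise ValidationError(f"unknown localization {self.localization!r}")

    @property
    def vmax_umol_min_mg(self) -> float:
        """Effective maximal rate in umol/min per mg protein (microsomal or
        cytosolic per `localization`), with ISEF applied where present."""
        v = self.vmax * _VMAX_UNIT_TO_UMOL[self.vmax_unit]
        if self.isef is not None:
            v = apply_isef(v, self.isef)
        return v

    @property
    def is_cyp3a4(self) -> bool:
        return self.enzyme.upper() == "CYP3A4"

    @property
    def key(self) -> str:
        return f"{self.enzyme}:{self.reaction}"


@dataclass
class CompoundModel:
    """Physicochemical + ADME parameter set for one drug."""

    name: str
    molecular_weight: float  # g/mol
    effective_molecular_weight: float
    log_p: float
    pka: float
    ionization: str  # only "monoprotic-base" supported
    water_solubility: float  # mg/mL
    fraction_unbound: float
    intestinal_permeability: float  # cm/min
    gfr_fraction: float
    fu_incubation: float
    pathways: list[MetabolicPathway] = field(default_factory=list)
    additional_hepatic_clearance: float = 0.0  # mL/min/kg, plasma-driven
    blood_plasma_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.fraction_unbound <= 1:
            raise ValidationError("fraction_unbound must be in (0, 1]")
        if not 0 <= self.gfr_fraction <= 1.5:
            raise ValidationError("gfr_fraction out of range")
        if not self.molecular_weight > self.effective_molecular_weight > 0:
            raise ValidationError("require MW > EMW > 0")
        if self.water_solubility <= 0:
            raise ValidationError("solubility must be > 0")
        if self.additional_hepatic_clearance < 0:
            raise ValidationError("additional hepatic clearance must be >= 0")

    def pathway(self, enzyme: str) -> MetabolicPathway:
        """First pathway catalysed by `enzyme` (convenience accessor)."""
        for p in self.pathways:
            if p.enzyme.upper() == enzyme.upper():
                return p
        raise KeyError(enzyme)

    def product_names(self) -> set[str]:
        return {p.product for p in self.pathways}

    def to_dict(self) -> dict:
        return asdict(self)


def _pathway_from_toml(block: dict, fu_incubation: float, correct_all_km: bool) -> MetabolicPathway:
    km_apparent = block.get("km_apparent_umol_l")
    km = block.get("km_umol_l")
    if km is None:
        km = correct_km(km_apparent, fu_incubation)
    elif correct_all_km and km_apparent is None:
        # flag: also correct rows tabulated without an apparent value
        km = correct_km(km, fu_incubation)
    return MetabolicPathway(
        enzyme=block["enzyme"],
        reaction=block["reaction"],
        system=block["system"],
        km=float(km),
        vmax=float(block["vmax"]),
        vmax_unit=block["vmax_unit"],
        localization=block["localization"],
        product=block.get("product", SINK),
        km_apparent=km_apparent,
        isef=block.get("isef"),
        enzyme_content=block.get("enzyme_content_pmol_mg"),
    )


def load_compound(source, *, correct_all_km: bool = False) -> CompoundModel:
    """Load a compound from a plain-text (TOML) parameter file.

    `source` is a path, file object opened in binary mode, or an
    already-parsed mapping.  With ``correct_all_km=True`` the fu,inc
    binding correction is also applied to Km rows tabulated without an
    apparent value (off by default: the tabulated input is authoritative).
    """
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = tomllib.load(source)
    else:
        with open(source, "rb") as fh:
            doc = tomllib.load(fh)
    fu_inc = float(doc.get("fu_incubation", 1.0))
    pathways = [
        _pathway_from_toml(b, fu_inc, correct_all_km) for b in doc.get("pathway", [])
    ]
    return CompoundModel(
        name=doc["name"],
        molecular_weight=float(doc["molecular_weight"]),
        effective_molecular_weight=float(doc["effective_molecular_weight"]),
        log_p=float(doc["log_p"]),
        pka=float(doc["pka"]),
        ionization=doc.get("ionization", "monoprotic-base"),
        water_solubility=float(doc["water_solubility_mg_ml"]),
        fraction_unbound=float(doc["fraction_unbound"]),
        intestinal_permeability=float(doc["intestinal_permeability_cm_min"]),
        gfr_fraction=float(doc["gfr_fraction"]),
        fu_incubation=fu_inc,
        pathways=pathways,
        additional_hepatic_clearance=float(
            doc.get("additional_hepatic_clearance_ml_min_kg", 0.0)
        ),
        blood_plasma_ratio=float(doc.get("blood_plasma_ratio", 1.0)),
    )


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def compound_to_toml(model: CompoundModel) -> str:
    """Serialize a compound to the plain-text config dialect consumed by
    :func:`load_compound` (lossless round trip)."""
    lines = [
        f"name = {_toml_scalar(model.name)}",
        f"molecular_weight = {_toml_scalar(model.molecular_weight)}",
        f"effective_molecular_weight = {_toml_scalar(model.effective_molecular_weight)}",
        f"log_p = {_toml_scalar(model.log_p)}",
        f"pka = {_toml_scalar(model.pka)}",
        f"ionization = {_toml_scalar(model.ionization)}",
        f"water_solubility_mg_ml = {_toml_scalar(model.water_solubility)}",
        f"fraction_unbound = {_toml_scalar(model.fraction_unbound)}",
        f"intestinal_permeability_cm_min = {_toml_scalar(model.intestinal_permeability)}",
        f"gfr_fraction = {_toml_scalar(model.gfr_fraction)}",
        f"fu_incubation = {_toml_scalar(model.fu_incubation)}",
        f"blood_plasma_ratio = {_toml_scalar(model.blood_plasma_ratio)}",
        "additional_hepatic_clearance_ml_min_kg = "
        + _toml_scalar(model.additional_hepatic_clearance),
    ]
    for p in model.pathways:
        lines += ["", "[[pathway]]"]
        lines.append(f"enzyme = {_toml_scalar(p.enzyme)}")
        lines.append(f"reaction = {_toml_scalar(p.reaction)}")
        lines.append(f"system = {_toml_scalar(p.system)}")
        if p.km_apparent is not None:
            lines.append(f"km_apparent_umol_l = {_toml_scalar(p.km_apparent)}")
        lines.append(f"km_umol_l = {_toml_scalar(p.km)}")
        lines.append(f"vmax = {_toml_scalar(p.vmax)}")
        lines.append(f"vmax_unit = {_toml_scalar(p.vmax_unit)}")
        if p.isef is not None:
            lines.append(f"isef = {_toml_scalar(p.isef)}")
        lines.append(f"localization = {_toml_scalar(p.localization)}")
        if p.enzyme_content is not None:
            lines.append(f"enzyme_content_pmol_mg = {_toml_scalar(p.enzyme_content)}")
        lines.append(f"product = {_toml_scalar(p.product)}")
    return "\n".join(lines) + "\n"


def _load_packaged(name: str, **kw) -> CompoundModel:
    ref = resources.files("halopbpk.data.compounds") / name
    with ref.open("rb") as fh:
        return load_compound(fh, **kw)


def haloperidol_model(**kw) -> CompoundModel:
    """The fully parameterized haloperidol model (six hepatic pathways plus
    renal filtration)."""
    return _load_packaged("haloperidol.toml", **kw)


def reduced_haloperidol_model(**kw) -> CompoundModel:
    """The reduced-haloperidol metabolite model (CYP3A4 back-oxidation to
    haloperidol plus a lumped linear hepatic clearance)."""
    return _load_packaged("reduced_haloperidol.toml", **kw)
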