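"""Virtual individuals and populations.

A :class:`Physiology` is one virtual individual: organ volumes, regional
blood flows, tissue compositions, glomerular filtration rate, and the liver
protein-scaling constants used by in-vitro-to-in-vivo extrapolation.
Reference values for a ~70 kg adult are embedded as package data (see
``data/reference/organs.csv`` for sources) and scaled to the requested
demographics: volumes linearly with body weight, flows and GFR with the
usual allometric exponent 0.75.

Populations are sampled with uniform (or truncated-normal) anthropometrics
over the study ranges and log-normal per-pathway enzyme-activity
multipliers (median 1).  The tuberculosis disease modification is a plasma
protein scaling factor applied to a compound's unbound fraction.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .errors import ValidationError

__all__ = [
    "TissueComposition",
    "Organ",
    "Physiology",
    "build_reference_individual",
    "sample_population",
    "apply_plasma_protein_scaling",
    "population_to_csv",
    "REFERENCE_BODY_WEIGHT",
    "REFERENCE_HEIGHT",
    "REFERENCE_GFR_ML_MIN",
    "REFERENCE_CARDIAC_OUTPUT_L_H",
]

REFERENCE_BODY_WEIGHT = 70.0  # kg
REFERENCE_HEIGHT = 176.0  # cm
REFERENCE_GFR_ML_MIN = 110.0
REFERENCE_CARDIAC_OUTPUT_L_H = 336.0  # 5.6 L/min
REFERENCE_HEMATOCRIT = 0.45
REFERENCE_MPPGL = 40.0  # mg microsomal protein / g liver (literature standard)
REFERENCE_CPPGL = 75.4  # mg cytosolic protein / g liver
BLOOD_VOLUME_L = 5.2  # arterial 1.7 + venous 3.5 at reference weight
ARTERIAL_FRACTION = 1.7 / 5.2

_AGE_RANGE = (18.0, 70.0)
_WEIGHT_RANGE = (43.0, 92.0)


@dataclass(frozen=True)
class TissueComposition:
    """Rodgers-Rowland composition constants for one tissue."""

    f_water_extracellular: float
    f_water_intracellular: float
    f_neutral_lipid: float
    f_neutral_phospholipid: float
    acidic_phospholipid: float  # mg/g

    def __post_init__(self) -> None:
        for name in (
            "f_water_extracellular",
            "f_water_intracellular",
            "f_neutral_lipid",
            "f_neutral_phospholipid",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} outside [0, 1]")
        if self.f_water_extracellular + self.f_water_intracellular > 1:
            raise ValidationError("water fractions sum above 1")


@dataclass(frozen=True)
class Organ:
    name: str
    volume: float  # L
    blood_flow: float  # L/h (arterial inflow; lung carries total CO)
    composition: TissueComposition
    portal: bool = False


def _read_packaged_csv(name: str) -> list[dict]:
    ref = resources.files("halopbpk.data.reference") / name
    with ref.open("r", encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    return list(csv.DictReader(io.StringIO("".join(lines))))


def _load_compositions() -> dict[str, TissueComposition]:
    out = {}
    for row in _read_packaged_csv("tissue_composition.csv"):
        out[row["tissue"]] = TissueComposition(
            f_water_extracellular=float(row["f_water_extracellular"]),
            f_water_intracellular=float(row["f_water_intracellular"]),
            f_neutral_lipid=float(row["f_neutral_lipid"]),
            f_neutral_phospholipid=float(row["f_neutral_phospholipid"]),
            acidic_phospholipid=float(row["acidic_phospholipid_mg_g"]),
        )
    return out


_COMPOSITIONS = _load_compositions()
_ORGAN_TABLE = _read_packaged_csv("organs.csv")

#: erythrocyte composition for the acidic-phospholipid association constant
BLOOD_CELL_COMPOSITION = _COMPOSITIONS["blood_cells"]


@dataclass
class Physiology:
    """One virtual individual."""

    sex: str
    age: float  # years
    body_weight: float  # kg
    height: float  # cm
    organs: dict[str, Organ]
    hematocrit: float = REFERENCE_HEMATOCRIT
    gfr: float = REFERENCE_GFR_ML_MIN  # mL/min
    liver_weight: float = 1800.0  # g
    mppgl: float = REFERENCE_MPPGL
    cppgl: float = REFERENCE_CPPGL
    arterial_volume: float = BLOOD_VOLUME_L * ARTERIAL_FRACTION
    venous_volume: float = BLOOD_VOLUME_L * (1 - ARTERIAL_FRACTION)
    plasma_protein_scale: float = 1.0
    pathway_activity_multipliers: dict[str, float] = field(default_factory=dict)
    label: str = "mean"

    def __post_init__(self) -> None:
        if not 0 < self.hematocrit < 1:
            raise ValidationError("hematocrit must be in (0, 1)")
        if self.plasma_protein_scale <= 0:
            raise ValidationError("plasma_protein_scale must be > 0")
        for org in self.organs.values():
            if org.volume <= 0 or org.blood_flow <= 0:
                raise ValidationError(f"{org.name}: volumes/flows must be > 0")
        if abs(self.systemic_flow - self.cardiac_output) > 0.01 * self.cardiac_output:
            raise ValidationError("organ flows do not balance cardiac output")

    @property
    def cardiac_output(self) -> float:
        """Total blood flow (L/h), carried by the lung."""
        return self.organs["lung"].blood_flow

    @property
    def systemic_flow(self) -> float:
        """Sum of systemic organ inflows (hepatic artery + portal organs +
        everything else); equals venous return."""
        return sum(o.blood_flow for n, o in self.organs.items() if n != "lung")

    @property
    def portal_flow(self) -> float:
        return sum(o.blood_flow for o in self.organs.values() if o.portal)

    @property
    def liver_total_flow(self) -> float:
        return self.organs["liver"].blood_flow + self.portal_flow

    def multiplier(self, pathway_key: str) -> float:
        return self.pathway_activity_multipliers.get(pathway_key, 1.0)


def build_reference_individual(
    sex: str = "male",
    age: float = 30.0,
    body_weight: float = REFERENCE_BODY_WEIGHT,
    height: float = REFERENCE_HEIGHT,
    *,
    allow_out_of_range: bool = False,
    plasma_protein_scale: float = 1.0,
    label: str = "mean",
) -> Physiology:
    """Deterministically construct one virtual individual.

    Organ volumes scale linearly with body weight from the embedded
    reference tables; blood flows and GFR scale with weight^0.75.  Age and
    sex are carried as metadata (no ontogeny is modelled).  Demographics
    outside the study ranges (age 18-70 y, weight 43-92 kg) require
    ``allow_out_of_range=True``.
    """
    if not allow_out_of_range:
        if not _AGE_RANGE[0] <= age <= _AGE_RANGE[1]:
            raise ValidationError(f"age {age} outside {_AGE_RANGE}")
        if not _WEIGHT_RANGE[0] <= body_weight <= _WEIGHT_RANGE[1]:
            raise ValidationError(f"body weight {body_weight} outside {_WEIGHT_RANGE}")
    size = body_weight / REFERENCE_BODY_WEIGHT
    flow_scale = size**0.75
    organs = {}
    for row in _ORGAN_TABLE:
        name = row["organ"]
        organs[name] = Organ(
            name=name,
            volume=float(row["volume_l"]) * size,
            blood_flow=float(row["flow_fraction"])
            * REFERENCE_CARDIAC_OUTPUT_L_H
            * flow_scale,
            composition=_COMPOSITIONS[row["composition"]],
            portal=row["portal"] == "1",
        )
    return Physiology(
        sex=sex,
        age=age,
        body_weight=body_weight,
        height=height,
        organs=organs,
        gfr=REFERENCE_GFR_ML_MIN * flow_scale,
        liver_weight=1000.0 * organs["liver"].volume,
        arterial_volume=BLOOD_VOLUME_L * ARTERIAL_FRACTION * size,
        venous_volume=BLOOD_VOLUME_L * (1 - ARTERIAL_FRACTION) * size,
        plasma_protein_scale=plasma_protein_scale,
        label=label,
    )


def sample_population(
    n: int,
    demographic_ranges: dict | None = None,
    variability_cv: float = 0.45,
    seed: int | np.random.Generator = 0,
    *,
    pathways: tuple[str, ...] = (
        "CYP3A4",
        "CBR1",
        "UGT1A4",
        "UGT1A9",
        "UGT2B7",
    ),
    distribution: str = "uniform",
    plasma_protein_scale: float = 1.0,
) -> list[Physiology]:
    """Sample `n` virtual individuals.

    Weight and age are drawn uniformly (or truncated-normally) within
    `demographic_ranges` (defaults to the study ranges); per-enzyme
    activity multipliers are drawn log-normally with coefficient of
    variation `variability_cv` and median 1.  Fully reproducible for a
    fixed seed.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if variability_cv < 0:
        raise ValidationError("CV must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ranges = dict(demographic_ranges or {})
    age_lo, age_hi = ranges.get("age", _AGE_RANGE)
    wt_lo, wt_hi = ranges.get("weight", _WEIGHT_RANGE)
    sigma = np.sqrt(np.log1p(variability_cv**2))

    def _draw(lo: float, hi: float, size: int) -> np.ndarray:
        if lo == hi:
            return np.full(size, lo)
        if distribution == "uniform":
            return rng.uniform(lo, hi, size)
        if distribution == "truncated-normal":
            mu, sd = (lo + hi) / 2, (hi - lo) / 4
            out = np.empty(size)
            for i in range(size):
                x = rng.normal(mu, sd)
                while not lo <= x <= hi:
                    x = rng.normal(mu, sd)
                out[i] = x
            return out
        raise ValidationError(f"unknown distribution {distribution!r}")

    ages = _draw(age_lo, age_hi, n)
    weights = _draw(wt_lo, wt_hi, n)
    pop = []
    for i in range(n):
        mult = {
            p: float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
            for p in pathways
        }
        ind = build_reference_individual(
            sex="male",
            age=float(ages[i]),
            body_weight=float(weights[i]),
            height=REFERENCE_HEIGHT,
            allow_out_of_range=True,
            plasma_protein_scale=plasma_protein_scale,
            label=f"id{i}",
        )
        pop.append(replace(ind, pathway_activity_multipliers=mult))
    return pop


def apply_plasma_protein_scaling(fu: float, scale: float) -> float:
    """Adjust a compound's plasma unbound fraction for an altered plasma
    binding-protein level.

    `scale` multiplies the binding-protein concentration; at constant
    affinity the unbound fraction becomes ``fu / (fu + scale * (1 - fu))``:
    identity at scale 1, monotonically decreasing in scale, limit 0 as
    scale grows.  Hypoproteinaemia (scale < 1) raises fu.
    """
    if not 0 < fu <= 1:
        raise ValidationError("fu must be in (0, 1]")
    if scale <= 0:
        raise ValidationError("scale must be > 0")
    return fu / (fu + scale * (1.0 - fu))


def population_to_csv(population: list[Physiology], path) -> None:
    """Export one row per individual: id, demographics, multipliers."""
    keys = sorted({k for p in population for k in p.pathway_activity_multipliers})
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "sex", "age", "body_weight_kg", "height_cm"] + keys)
        for p in population:
            w.writerow(
                [p.label, p.sex, f"{p.age:.2f}", f"{p.body_weight:.2f}", p.height]
                + [f"{p.multiplier(k):.6f}" for k in keys]
            )
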