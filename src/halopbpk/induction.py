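"""CYP3A4-induction drug-drug interaction (rifampicin co-treatment).

Steady-state rifampicin (600 mg) is represented as a static fold increase
of every CYP3A4 pathway's effective Vmax — the parent's two oxidations and
the metabolite's back-oxidation alike.  The fold is a single calibrated
constant chosen so that the simulated induced/control AUC ratio on the
5 mg IV tuberculosis scenario matches the reported steady-state ratio;
onset/offset kinetics of induction are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from scipy.optimize import brentq

from .engine import SimulationSpec, simulate
from .errors import CalibrationError, ConfigurationError, ValidationError
from .scenarios import build_spec, get_scenario, scenario_nca

__all__ = [
    "InductionSetting",
    "apply_induction",
    "calibrate_induction",
    "dose_adjustment_scan",
]


@dataclass(frozen=True)
class InductionSetting:
    """A static enzyme-induction setting."""

    target_enzyme: str = "CYP3A4"
    fold: float = 1.0

    def __post_init__(self) -> None:
        if self.fold < 1:
            raise ValidationError("induction fold must be >= 1")
        if self.target_enzyme.upper() != "CYP3A4":
            raise ValidationError("only CYP3A4 induction is supported")


def apply_induction(spec: SimulationSpec, setting: InductionSetting) -> SimulationSpec:
    """Return a spec with every CYP3A4 pathway's Vmax_eff multiplied by
    the fold; all other pathways untouched."""
    if not any(p.is_cyp3a4 for c in spec.compounds for p in c.pathways):
        raise ConfigurationError("spec contains no CYP3A4 pathway to induce")
    return replace(
        spec, cyp3a4_induction_fold=spec.cyp3a4_induction_fold * setting.fold
    )


def _auc_for_fold(scenario_id: str, fold: float, rtol: float | None) -> float:
    scenario = get_scenario(scenario_id)
    spec = build_spec(scenario, induction_fold=fold, rtol=rtol)
    return scenario_nca(scenario, simulate(spec)).auc_inf


def calibrate_induction(
    target_auc_ratio: float = 0.60,
    scenario_id: str = "iv_5mg_tb_control",
    fold_bracket: tuple[float, float] = (1.0, 50.0),
    xtol: float = 1e-3,
    rtol: float | None = None,
) -> float:
    """Find the CYP3A4 fold whose simulated AUC(induced)/AUC(control)
    matches the target on the given scenario (scalar root find)."""
    if not 0 < target_auc_ratio <= 1:
        raise CalibrationError("target AUC ratio must be in (0, 1]")
    if target_auc_ratio == 1.0:
        return 1.0
    auc_control = _auc_for_fold(scenario_id, 1.0, rtol)

    def f(fold: float) -> float:
        return _auc_for_fold(scenario_id, fold, rtol) / auc_control - target_auc_ratio

    lo, hi = fold_bracket
    if f(hi) > 0:
        raise CalibrationError(
            f"target ratio {target_auc_ratio} unreachable within fold <= {hi}"
        )
    return float(brentq(f, lo, hi, xtol=xtol))


def dose_adjustment_scan(
    increases_percent=(50.0, 75.0, 100.0),
    scenario_id: str = "iv_5mg_tb_control",
    induction_fold: float | None = None,
    rtol: float | None = None,
) -> dict:
    """AUC per dose-adjustment arm under calibrated induction.

    Simulates the control arm (no rifampicin, base dose) and induced arms
    at base dose x (1 + increase); reports each arm's AUC and which arm
    comes closest to restoring the control exposure.
    """
    scenario = get_scenario(scenario_id)
    control = scenario_nca(
        scenario, simulate(build_spec(scenario, rtol=rtol))
    ).auc_inf
    arms = {}
    for inc in (0.0, *increases_percent):
        spec = build_spec(
            scenario,
            induction_fold=induction_fold,
            dose_multiplier=1.0 + inc / 100.0,
            rtol=rtol,
        )
        if induction_fold is None:
            # use the frozen calibrated default
            from .config import default

            spec = replace(
                spec,
                cyp3a4_induction_fold=default(
                    "calibration", "rifampicin_induction_fold"
                ),
            )
        pk = scenario_nca(scenario, simulate(spec))
        arms[inc] = pk.auc_inf
    closest = min(arms, key=lambda inc: abs(arms[inc] - control))
    return {"control_auc": control, "arms": arms, "closest_arm_percent": closest}
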