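"""Model calibration.

The only metabolic degree of freedom is a single global scaling factor
applied to every pathway's Vmax_eff.  It stands in for the unprinted
in-vivo enzyme-abundance information of the source platform and is fixed
once by matching the mean-individual IV clearance of the 0.125 mg/kg
study; afterwards it is frozen (see data/defaults.toml) and reused by
every scenario.
"""

from __future__ import annotations

from scipy.optimize import brentq

from .config import default
from .engine import simulate
from .errors import CalibrationError
from .scenarios import build_spec, get_scenario, scenario_nca

__all__ = ["calibrate_metabolic_scale"]


def calibrate_metabolic_scale(
    target_cl_ml_min_kg: float | None = None,
    scenario_id: str | None = None,
    bracket: tuple[float, float] = (0.2, 50.0),
    xtol: float = 1e-4,
    rtol: float | None = None,
) -> float:
    """Root-find the global metabolic scale so that the simulated NCA
    clearance of the calibration scenario matches the observed mean.

    Returns the scale; raises :class:`CalibrationError` if the target is
    outside the reachable range (hepatic clearance is bounded by liver
    blood flow, so an over-ambitious target cannot be met by any scale).
    """
    target = (
        target_cl_ml_min_kg
        if target_cl_ml_min_kg is not None
        else default("calibration", "cl_target_ml_min_kg")
    )
    sid = scenario_id or default("calibration", "calibration_scenario")
    scenario = get_scenario(sid)

    def cl_for(scale: float) -> float:
        spec = build_spec(scenario, global_metabolic_scale=scale, rtol=rtol)
        return scenario_nca(scenario, simulate(spec)).cl

    def f(scale: float) -> float:
        return cl_for(scale) - target

    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"clearance target {target} mL/min/kg not bracketed by scales "
            f"[{lo}, {hi}] (CL range {f_lo + target:.3g}..{f_hi + target:.3g})"
        )
    return float(brentq(f, lo, hi, xtol=xtol, rtol=1e-5))
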