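"""Non-compartmental analysis of concentration-time profiles.

AUC by the linear-up/log-down trapezoid (the observed-data standard:
linear when concentration rises or is flat, logarithmic when it falls),
terminal slope by unweighted log-linear least squares over the last
`lambda_z_points` samples, extrapolation C_last / lambda_z, clearance
dose / AUC_inf normalized to body weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import ConcentrationTimeProfile
from .errors import InvalidParameterError, LambdaZError

__all__ = ["PKParams", "run_nca", "auc_trapezoid"]


@dataclass
class PKParams:
    """NCA outputs for one profile."""

    auc_0_t: float  # ng*h/mL
    auc_inf: float  # ng*h/mL
    cmax: float  # ng/mL
    tmax: float  # h
    lambda_z: float  # 1/h
    t_half: float  # h
    cl: float  # mL/min/kg (apparent CL/F after oral dosing)
    c_tend: float  # ng/mL, last simulated/observed concentration
    dose: float  # mg
    body_weight: float  # kg

    def as_dict(self) -> dict[str, float]:
        return {
            "auc_0_t": self.auc_0_t,
            "auc_inf": self.auc_inf,
            "cmax": self.cmax,
            "tmax": self.tmax,
            "lambda_z": self.lambda_z,
            "t_half": self.t_half,
            "cl": self.cl,
            "c_tend": self.c_tend,
        }


def auc_trapezoid(times: np.ndarray, conc: np.ndarray, method: str = "linuplogdown") -> float:
    """AUC over the sampled interval.

    "linuplogdown": linear trapezoid on rising/flat intervals, log
    trapezoid on falling intervals with both endpoints positive;
    "linear": plain trapezoid throughout.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if method == "linear":
        return float(np.trapezoid(c, t))
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c1 > 0 and c2 > 0:
            auc += dt * (c1 - c2) / np.log(c1 / c2)
        else:
            auc += dt * (c1 + c2) / 2.0
    return float(auc)


def run_nca(
    profile: ConcentrationTimeProfile,
    dose: float,
    body_weight: float,
    lambda_z_points: int = 4,
    method: str = "linuplogdown",
) -> PKParams:
    """Non-compartmental parameters of one profile.

    `dose` in mg, `body_weight` in kg.  Requires at least 4 positive
    concentrations and a decaying terminal phase over the lambda_z window.
    """
    t = profile.times
    c = profile.concentrations
    pos = c > 0
    if int(pos.sum()) < 4:
        raise InvalidParameterError("need >= 4 positive concentrations for NCA")
    if dose <= 0 or body_weight <= 0:
        raise InvalidParameterError("dose and body weight must be > 0")
    auc_0_t = auc_trapezoid(t, c, method)
    i_max = int(np.argmax(c))
    cmax, tmax = float(c[i_max]), float(t[i_max])
    # terminal slope on the last `lambda_z_points` positive samples
    idx = np.flatnonzero(pos)[-lambda_z_points:]
    if len(idx) < 2:
        raise LambdaZError("not enough positive terminal samples")
    slope, _ = np.polyfit(t[idx], np.log(c[idx]), 1)
    lambda_z = -float(slope)
    if lambda_z <= 0:
        raise LambdaZError(
            f"non-decaying tail (lambda_z = {-lambda_z:.3g}/h <= 0) over the "
            f"last {len(idx)} samples"
        )
    c_last = float(c[pos][-1])
    auc_inf = auc_0_t + c_last / lambda_z
    # dose [mg] -> ng; AUC [ng*h/mL]; CL in mL/min/kg
    cl = dose * 1e6 / auc_inf / 60.0 / body_weight
    return PKParams(
        auc_0_t=auc_0_t,
        auc_inf=auc_inf,
        cmax=cmax,
        tmax=tmax,
        lambda_z=lambda_z,
        t_half=float(np.log(2.0) / lambda_z),
        cl=cl,
        c_tend=float(c[-1]),
        dose=dose,
        body_weight=body_weight,
    )
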