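"""Model-qualification statistics and acceptance rules.

Predicted-vs-observed ratio, prediction error (PE%), mean fold error
(MFE), root-mean-square error (RMSE), induction interaction ratios
(AUC, C_tEnd, T1/2), the two-fold acceptance check, and numeric
visual-predictive-check percentile bands.

MFE convention: the reported mean fold errors equal the arithmetic mean of
the per-study predicted/observed ratios; that is the default ("ratio-mean"
mode).  The literal quotient-of-means form is available as a mode flag;
the two coincide when all observed values are equal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .engine import ConcentrationTimeProfile
from .errors import InvalidParameterError
from .nca import PKParams

__all__ = [
    "EvaluationRecord",
    "AggregateMetrics",
    "ratio",
    "prediction_error",
    "fold_error",
    "mfe",
    "rmse",
    "interaction_ratios",
    "two_fold_check",
    "vpc_bands",
]


def ratio(predicted: float, observed: float) -> float:
    """Predicted / observed."""
    if observed <= 0:
        raise InvalidParameterError("observed must be > 0")
    return predicted / observed


def prediction_error(predicted: float, observed: float, signed: bool = False) -> float:
    """Prediction error in percent; magnitudes by default, signed on
    request."""
    if observed <= 0:
        raise InvalidParameterError("observed must be > 0")
    pe = (predicted - observed) / observed * 100.0
    return pe if signed else abs(pe)


def fold_error(predicted: float, observed: float) -> float:
    """max(ratio, 1/ratio) >= 1."""
    r = ratio(predicted, observed)
    if r <= 0:
        raise InvalidParameterError("predicted must be > 0 for a fold error")
    return max(r, 1.0 / r)


@dataclass
class EvaluationRecord:
    """One predicted-vs-observed comparison."""

    scenario_id: str
    parameter: str  # AUC_inf | Cmax | CL | T_half | C_tEnd
    predicted: float
    observed: float

    @property
    def ratio(self) -> float:
        return ratio(self.predicted, self.observed)

    @property
    def pe_percent(self) -> float:
        return prediction_error(self.predicted, self.observed)

    @property
    def fold_error(self) -> float:
        return fold_error(self.predicted, self.observed)


@dataclass
class AggregateMetrics:
    mfe: float
    rmse: float
    n: int


def _check_records(records: Sequence[EvaluationRecord]) -> None:
    if not records:
        raise InvalidParameterError("empty record list")


def mfe(records: Sequence[EvaluationRecord], mode: str = "ratio-mean") -> float:
    """Mean fold error of a set of predicted/observed pairs."""
    _check_records(records)
    if mode == "ratio-mean":
        return float(np.mean([r.ratio for r in records]))
    if mode == "quotient-of-means":
        return float(
            np.mean([r.predicted for r in records])
            / np.mean([r.observed for r in records])
        )
    raise InvalidParameterError(f"unknown MFE mode {mode!r}")


def rmse(records: Sequence[EvaluationRecord]) -> float:
    """Root-mean-square of observed - predicted (units of the parameter)."""
    _check_records(records)
    d = np.array([r.observed - r.predicted for r in records])
    return float(np.sqrt(np.mean(d**2)))


def aggregate(records: Sequence[EvaluationRecord], mode: str = "ratio-mean") -> AggregateMetrics:
    return AggregateMetrics(mfe=mfe(records, mode), rmse=rmse(records), n=len(records))


def interaction_ratios(induced: PKParams, control: PKParams) -> dict[str, float]:
    """Induced/control quotients for AUC_inf, C_tEnd and T1/2."""
    for name, pk in (("induced", induced), ("control", control)):
        for f in ("auc_inf", "c_tend", "t_half"):
            if getattr(pk, f) is None or not np.isfinite(getattr(pk, f)):
                raise InvalidParameterError(f"{name}.{f} missing")
    return {
        "auc_ratio": induced.auc_inf / control.auc_inf,
        "c_tend_ratio": induced.c_tend / control.c_tend,
        "t_half_ratio": induced.t_half / control.t_half,
    }


def two_fold_check(records: Sequence[EvaluationRecord]) -> tuple[bool, float]:
    """(pass, worst fold error): pass iff every fold error <= 2."""
    _check_records(records)
    worst = max(r.fold_error for r in records)
    return worst <= 2.0, worst


def vpc_bands(
    profiles: Iterable[ConcentrationTimeProfile],
    percentiles: tuple[float, float] = (5.0, 95.0),
    observed: ConcentrationTimeProfile | None = None,
) -> dict:
    """Pointwise percentile curves over >= 10 individual profiles on a
    common grid; optionally the fraction of observed points inside the
    band (observed times must lie on the grid)."""
    profs = list(profiles)
    if len(profs) < 10:
        raise InvalidParameterError("need >= 10 profiles for a percentile band")
    t0 = profs[0].times
    for p in profs[1:]:
        if len(p.times) != len(t0) or not np.allclose(p.times, t0):
            raise InvalidParameterError("profiles are not on a common time grid")
    arr = np.vstack([p.concentrations for p in profs])
    lo = np.percentile(arr, percentiles[0], axis=0)
    hi = np.percentile(arr, percentiles[1], axis=0)
    out = {
        "lower": ConcentrationTimeProfile(
            profs[0].compound, t0, lo, f"p{percentiles[0]:g}"
        ),
        "upper": ConcentrationTimeProfile(
            profs[0].compound, t0, hi, f"p{percentiles[1]:g}"
        ),
    }
    if observed is not None:
        inside = 0
        for t, c in zip(observed.times, observed.concentrations):
            i = int(np.argmin(np.abs(t0 - t)))
            if not np.isclose(t0[i], t):
                raise InvalidParameterError("observed time off the simulation grid")
            inside += bool(lo[i] <= c <= hi[i])
        out["coverage"] = inside / len(observed.times)
    return out
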