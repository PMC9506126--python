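"""Shipped study tables and synthetic observed data.

The published study catalog, predicted/observed PK aggregates and
interaction summary are shipped as plain-text CSV package data and loaded
into pandas frames by :func:`load_fixture_tables`; a manifest of SHA-256
checksums guards against silent corruption.

Real concentration-time curves from the source studies are not shipped
(figure-digitized values are unreliable); instead
:func:`generate_observed_profile` draws synthetic "observed" profiles with
the statistical structure the analysis assumes — sparse samples of a
bi-exponential decline under multiplicative log-normal noise with a lower
limit of quantification — and :func:`nca_recovery_experiment` quantifies
how well the NCA stage recovers known exposure parameters from them.
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from importlib import resources

from .engine import ConcentrationTimeProfile
from .errors import PackagingError, ValidationError
from .nca import run_nca

__all__ = [
    "SyntheticObservedSpec",
    "FixtureTables",
    "load_fixture_tables",
    "generate_observed_profile",
    "biexponential",
    "nca_recovery_experiment",
]

_TABLE_FILES = {
    "scenarios": "clinical_studies.csv",
    "observed_iv": "pk_observed_iv.csv",
    "observed_oral": "pk_observed_oral.csv",
    "footers": "pk_footers.csv",
    "ddi_summary": "ddi_summary.csv",
    "ddi_ratios": "ddi_ratios.csv",
    "settings": "scenario_settings.csv",
}


def _read_table(name: str, verify: bool = True) -> pd.DataFrame:
    root = resources.files("halopbpk.data.tables")
    raw = (root / name).read_bytes()
    if verify:
        manifest = _load_manifest()
        digest = hashlib.sha256(raw).hexdigest()
        if name not in manifest:
            raise PackagingError(f"{name} missing from fixture manifest")
        if manifest[name] != digest:
            raise PackagingError(f"checksum mismatch for fixture {name}")
    return pd.read_csv(io.BytesIO(raw), comment="#")


def _load_manifest() -> dict[str, str]:
    root = resources.files("halopbpk.data.tables")
    out: dict[str, str] = {}
    with (root / "manifest.csv").open("r", encoding="utf-8") as fh:
        for row in csv.DictReader(ln for ln in fh if not ln.startswith("#")):
            out[row["file"]] = row["sha256"]
    return out


@dataclass
class FixtureTables:
    """All shipped tables, as pandas frames."""

    scenarios: pd.DataFrame
    observed_iv: pd.DataFrame
    observed_oral: pd.DataFrame
    footers: pd.DataFrame
    ddi_summary: pd.DataFrame
    ddi_ratios: pd.DataFrame
    settings: pd.DataFrame

    def observed(self, route: str) -> pd.DataFrame:
        return self.observed_iv if route == "iv" else self.observed_oral


def load_fixture_tables(verify: bool = True) -> FixtureTables:
    """Load every shipped table; `verify` checks SHA-256 against the
    manifest and raises :class:`PackagingError` on mismatch."""
    frames = {k: _read_table(v, verify) for k, v in _TABLE_FILES.items()}
    return FixtureTables(**frames)


@dataclass
class SyntheticObservedSpec:
    """Recipe for one synthetic observed profile.

    `coefficients` / `rates` parameterize the true curve
    C(t) = sum_i C_i exp(-lambda_i t) (ng/mL, 1/h); alternatively
    `true_profile` supplies an engine-simulated truth.  Noise is
    multiplicative log-normal with coefficient of variation `noise_cv`;
    samples below `lloq` are dropped.
    """

    sampling_times: tuple
    coefficients: tuple = ()
    rates: tuple = ()
    true_profile: ConcentrationTimeProfile | None = None
    noise_cv: float = 0.0
    lloq: float = 0.0
    seed: int = 0
    compound: str = "haloperidol"

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        t = np.asarray(self.sampling_times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValidationError("sampling times must be strictly increasing")
        if self.true_profile is None:
            if len(self.coefficients) != len(self.rates) or not self.rates:
                raise ValidationError("need matching coefficients and rates")
            if any(l <= 0 for l in self.rates):
                raise ValidationError("rate constants must be > 0")

    @property
    def true_auc_inf(self) -> float:
        """Closed-form AUC of the bi-exponential truth: sum C_i/lambda_i."""
        if self.true_profile is not None:
            raise ValidationError("analytic AUC only defined for coefficients")
        return float(sum(c / l for c, l in zip(self.coefficients, self.rates)))

    def true_concentrations(self, times: np.ndarray) -> np.ndarray:
        if self.true_profile is not None:
            return np.interp(
                times, self.true_profile.times, self.true_profile.concentrations
            )
        out = np.zeros_like(times, dtype=float)
        for c, l in zip(self.coefficients, self.rates):
            out += c * np.exp(-l * times)
        return out


def biexponential(a: float, alpha: float, b: float, beta: float):
    """Convenience constructor for a two-phase decline."""
    return (a, b), (alpha, beta)


def generate_observed_profile(
    spec: SyntheticObservedSpec, rng: np.random.Generator | None = None
) -> ConcentrationTimeProfile:
    """Draw one synthetic observed profile: C_obs(t_j) = C_true(t_j) exp(e_j)
    with e_j ~ N(0, sigma), sigma = sqrt(ln(1 + CV^2)); values below the
    LLOQ are dropped.  Reproducible under the spec seed."""
    rng = rng or np.random.default_rng(spec.seed)
    t = np.asarray(spec.sampling_times, dtype=float)
    c_true = spec.true_concentrations(t)
    if spec.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
        c_obs = c_true * np.exp(rng.normal(0.0, sigma, size=len(t)))
    else:
        c_obs = c_true.copy()
    keep = c_obs >= spec.lloq
    return ConcentrationTimeProfile(
        spec.compound, t[keep], c_obs[keep], label="synthetic-observed"
    )


def nca_recovery_experiment(
    spec: SyntheticObservedSpec,
    replicates: int,
    seed: int,
    dose_mg: float = 5.0,
    body_weight: float = 70.0,
    lambda_z_points: int = 4,
) -> dict:
    """Bias/precision of NCA exposure estimates on noisy synthetic data.

    Runs the NCA on `replicates` independent noisy draws of the profile
    and reports relative bias and CV of AUC_inf and t_half against the
    analytic truth (sum C_i/lambda_i; ln2 / smallest rate constant).
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    true_auc = spec.true_auc_inf
    true_thalf = float(np.log(2.0) / min(spec.rates))
    aucs, thalves = [], []
    for _ in range(replicates):
        prof = generate_observed_profile(spec, rng)
        pk = run_nca(prof, dose_mg, body_weight, lambda_z_points)
        aucs.append(pk.auc_inf)
        thalves.append(pk.t_half)
    aucs = np.asarray(aucs)
    thalves = np.asarray(thalves)
    return {
        "n": replicates,
        "auc_bias": float(aucs.mean() / true_auc - 1.0),
        "auc_cv": float(aucs.std(ddof=1) / aucs.mean()) if replicates > 1 else 0.0,
        "thalf_bias": float(thalves.mean() / true_thalf - 1.0),
        "thalf_cv": float(thalves.std(ddof=1) / thalves.mean())
        if replicates > 1
        else 0.0,
        "true_auc_inf": true_auc,
        "true_t_half": true_thalf,
    }
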