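"""Qualification statistics: ratio, PE, MFE, RMSE, interaction ratios,
two-fold rule, percentile bands."""

import numpy as np
import pytest

from halopbpk.engine import ConcentrationTimeProfile
from halopbpk.errors import InvalidParameterError
from halopbpk.evaluation import (
    EvaluationRecord,
    interaction_ratios,
    mfe,
    prediction_error,
    ratio,
    rmse,
    two_fold_check,
    vpc_bands,
)
from halopbpk.nca import PKParams


def _pk(auc, thalf, ctend):
    return PKParams(
        auc_0_t=auc * 0.9,
        auc_inf=auc,
        cmax=10.0,
        tmax=1.0,
        lambda_z=np.log(2) / thalf,
        t_half=thalf,
        cl=1.0,
        c_tend=ctend,
        dose=5.0,
        body_weight=70.0,
    )


def test_ratio_examples():
    assert round(ratio(168, 202), 2) == 0.83
    assert ratio(37.5, 37.5) == 1.0
    assert round(ratio(103.85, 174), 2) == 0.60
    with pytest.raises(InvalidParameterError):
        ratio(1.0, 0.0)


def test_prediction_error_examples():
    assert prediction_error(193, 202) == pytest.approx(4.5, abs=0.05)
    assert prediction_error(42.0, 42.0) == 0.0
    assert prediction_error(168, 202) == pytest.approx(16.8, abs=0.05)
    # signed variant keeps the sign
    assert prediction_error(168, 202, signed=True) < 0


def test_mfe_modes():
    equal = [EvaluationRecord("s", "AUC_inf", 10.0, 10.0) for _ in range(3)]
    assert mfe(equal) == pytest.approx(1.0)
    assert mfe(equal, mode="quotient-of-means") == pytest.approx(1.0)
    mixed = [
        EvaluationRecord("a", "AUC_inf", 50.0, 100.0),
        EvaluationRecord("b", "AUC_inf", 300.0, 100.0),
    ]
    assert mfe(mixed) == pytest.approx((0.5 + 3.0) / 2)
    assert mfe(mixed, mode="quotient-of-means") == pytest.approx(350.0 / 200.0)
    with pytest.raises(InvalidParameterError):
        mfe([])


def test_rmse_zero_for_perfect_predictions():
    recs = [EvaluationRecord("a", "CL", 3.0, 3.0), EvaluationRecord("b", "CL", 7.0, 7.0)]
    assert rmse(recs) == 0.0
    with pytest.raises(InvalidParameterError):
        rmse([])


def test_interaction_ratio_examples():
    induced = _pk(auc=103.85, thalf=4.76, ctend=0.5)
    control = _pk(auc=174.0, thalf=11.5, ctend=2.0)
    r = interaction_ratios(induced, control)
    assert round(r["auc_ratio"], 2) == 0.60
    assert round(r["t_half_ratio"], 2) == 0.41
    same = interaction_ratios(control, control)
    assert all(v == pytest.approx(1.0) for v in same.values())


def test_two_fold_check():
    ok = [EvaluationRecord("a", "AUC_inf", 100.0, 100.0)]
    passed, worst = two_fold_check(ok)
    assert passed and worst == pytest.approx(1.0)
    bad = ok + [EvaluationRecord("b", "AUC_inf", 210.0, 100.0)]
    passed, worst = two_fold_check(bad)
    assert not passed
    assert worst == pytest.approx(2.1)


class TestVpcBands:
    times = np.linspace(0.5, 24, 20)

    def _profiles(self, n, sigma, rng):
        base = 50 * np.exp(-0.2 * self.times)
        return [
            ConcentrationTimeProfile(
                "hal", self.times, base * np.exp(rng.normal(0, sigma, len(self.times))),
                label=f"id{i}",
            )
            for i in range(n)
        ]

    def test_identical_profiles_collapse_band(self):
        rng = np.random.default_rng(0)
        profs = self._profiles(12, 0.0, rng)
        bands = vpc_bands(profs)
        assert np.allclose(bands["lower"].concentrations, profs[0].concentrations)
        assert np.allclose(bands["upper"].concentrations, profs[0].concentrations)

    def test_constructed_points_inside_band_have_full_coverage(self):
        rng = np.random.default_rng(1)
        profs = self._profiles(50, 0.3, rng)
        bands = vpc_bands(profs)
        mid = ConcentrationTimeProfile(
            "hal",
            self.times,
            (bands["lower"].concentrations + bands["upper"].concentrations) / 2,
        )
        assert vpc_bands(profs, observed=mid)["coverage"] == 1.0

    def test_monte_carlo_coverage_matches_nominal(self):
        """Observed points drawn from the same log-normal law as 1000
        profiles fall inside the 5-95 band ~90% of the time."""
        rng = np.random.default_rng(2)
        profs = self._profiles(1000, 0.4, rng)
        base = 50 * np.exp(-0.2 * self.times)
        hits = []
        for _ in range(25):
            obs = ConcentrationTimeProfile(
                "hal", self.times, base * np.exp(rng.normal(0, 0.4, len(self.times)))
            )
            hits.append(vpc_bands(profs, observed=obs)["coverage"])
        assert np.mean(hits) == pytest.approx(0.90, abs=0.03)

    def test_mismatched_grids_rejected(self):
        rng = np.random.default_rng(3)
        profs = self._profiles(12, 0.1, rng)
        other = ConcentrationTimeProfile("hal", self.times + 0.1, profs[0].concentrations)
        with pytest.raises(InvalidParameterError):
            vpc_bands(profs[:-1] + [other])
        with pytest.raises(InvalidParameterError):
            vpc_bands(profs[:5])
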