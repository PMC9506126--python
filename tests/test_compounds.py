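"""Compound parameter sets and IVIVE derived-parameter arithmetic."""

import tomllib

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halopbpk.compounds import (
    apply_isef,
    compound_to_toml,
    convert_vmax_per_pmol,
    correct_km,
    cytosolic_reference_concentration,
    load_compound,
)
from halopbpk.errors import InvalidParameterError


@pytest.mark.parametrize(
    "km_apparent, fu_inc, expected",
    [(62, 0.35, 21.7), (80, 0.35, 28.0), (64, 0.35, 22.4), (123.4, 1.0, 123.4)],
)
def test_km_binding_correction(km_apparent, fu_inc, expected):
    assert correct_km(km_apparent, fu_inc) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("km, fu", [(-1, 0.35), (0, 0.35), (62, 0), (62, 1.5)])
def test_km_correction_rejects_bad_inputs(km, fu):
    with pytest.raises(InvalidParameterError):
        correct_km(km, fu)


@pytest.mark.parametrize(
    "v, content, expected", [(0.53, 460, 243.8), (0, 460, 0), (1.0, 1000, 1000)]
)
def test_vmax_unit_conversion(v, content, expected):
    assert convert_vmax_per_pmol(v, content) == pytest.approx(expected)


def test_vmax_unit_conversion_rejects_negative():
    with pytest.raises(InvalidParameterError):
        convert_vmax_per_pmol(-0.5, 460)


def test_cytosolic_reference_concentration():
    exact = cytosolic_reference_concentration(75, 75.4)
    assert exact == pytest.approx(5.655)
    # reported form truncates at 2 significant figures
    assert cytosolic_reference_concentration(75, 75.4, report=True) == 5.6
    assert cytosolic_reference_concentration(0, 75.4) == 0
    assert cytosolic_reference_concentration(100, 50) == pytest.approx(5.0)


@pytest.mark.parametrize(
    "v, isef, expected", [(600, 0.16, 96.0), (2300, 0.06, 138.0), (417.3, 1.0, 417.3)]
)
def test_isef_scaling(v, isef, expected):
    assert apply_isef(v, isef) == pytest.approx(expected)


def test_isef_outside_unit_interval_rejected():
    for isef in (0.0, -0.1, 1.2):
        with pytest.raises(InvalidParameterError):
            apply_isef(100.0, isef)


@settings(max_examples=50, deadline=None)
@given(
    km=st.floats(0.01, 1e4),
    fu=st.floats(0.01, 1.0),
)
def test_km_correction_shrinks_and_scales(km, fu):
    corrected = correct_km(km, fu)
    assert corrected <= km
    assert corrected == pytest.approx(km * fu)


class TestHaloperidolModel:
    def test_physicochemistry(self, hal):
        assert hal.molecular_weight == 376
        assert hal.effective_molecular_weight == pytest.approx(336.86)
        assert hal.log_p == pytest.approx(3.66)
        assert hal.pka == pytest.approx(8.65)
        assert hal.water_solubility == pytest.approx(0.0045)
        assert hal.fraction_unbound == pytest.approx(0.085)
        assert hal.intestinal_permeability == pytest.approx(3.09e-4)

    def test_pathway_catalog(self, hal):
        kms = sorted(p.km for p in hal.pathways)
        assert kms == sorted([21.7, 28.0, 88.0, 22.4, 61.0, 16.0, 64.0])
        cbr1 = hal.pathway("CBR1")
        assert cbr1.product == "reduced haloperidol"
        assert cbr1.localization == "cytosolic"

    def test_tabulated_km_match_binding_correction_at_printed_precision(self, hal):
        # every non-recombinant-or-not pathway with an apparent Km printed:
        # corrected = apparent * 0.35, rounded to the table's precision
        for p in hal.pathways:
            if p.km_apparent is None:
                continue
            corrected = correct_km(p.km_apparent, hal.fu_incubation)
            ndigits = 1 if p.km != int(p.km) else 0
            assert round(corrected, ndigits) == pytest.approx(p.km)

    def test_internal_rate_unit_conversion_is_lossless(self, hal):
        ugt1a4 = next(
            p for p in hal.pathways if p.enzyme == "UGT1A4" and "O-" in p.reaction
        )
        # 600 pmol/min/mg * 0.16 -> 96 pmol/min/mg -> 9.6e-5 umol/min/mg
        assert ugt1a4.vmax_umol_min_mg == pytest.approx(9.6e-5, rel=1e-10)
        cbr1 = hal.pathway("CBR1")
        assert cbr1.vmax_umol_min_mg == pytest.approx(1.30e-3, rel=1e-10)
        assert all(p.vmax_umol_min_mg > 0 for p in hal.pathways)

    def test_n_glucuronidation_km_as_tabulated_with_correction_flag(self):
        from halopbpk.compounds import haloperidol_model

        base = haloperidol_model()
        n_gluc = next(p for p in base.pathways if "N-gluc" in p.reaction)
        assert n_gluc.km == 64.0
        corrected = haloperidol_model(correct_all_km=True)
        n_gluc_c = next(p for p in corrected.pathways if "N-gluc" in p.reaction)
        assert n_gluc_c.km == pytest.approx(64.0 * 0.35)

    def test_serialization_round_trip(self, hal):
        doc = tomllib.loads(compound_to_toml(hal))
        again = load_compound(doc)
        assert again == hal


class TestReducedHaloperidolModel:
    def test_contents(self, rhal):
        assert rhal.fraction_unbound == pytest.approx(0.244)
        assert rhal.additional_hepatic_clearance == 5.0
        ox = rhal.pathway("CYP3A4")
        assert ox.product == "haloperidol"
        assert ox.km == 46.0
        assert ox.vmax == 98.0

    def test_round_trip(self, rhal):
        assert load_compound(tomllib.loads(compound_to_toml(rhal))) == rhal
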