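import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnctkit.dosimetry import (
    BeamSpec,
    DoseComponents,
    DoseScenario,
    KermaSet,
    WeightSet,
    beam_dose_components,
    boron_physical_dose,
    dose_report,
    effective_boron_concentration,
    photon_equivalent_dose,
    total_physical_dose,
)
from bnctkit.errors import ConfigurationError, InvalidInputError

BEAM = BeamSpec(flux=7.0e8, duration=3600.0, nonboron_dose_rate=1.0 / 3600.0)
KERMA = KermaSet()

component_floats = st.floats(0.0, 50.0, allow_nan=False)


class TestBoronPhysicalDose:
    def test_zero_concentration(self):
        assert boron_physical_dose(0.0, BEAM, KERMA) == 0.0

    def test_linearity_in_concentration(self):
        d1 = boron_physical_dose(5.0, BEAM, KERMA)
        d2 = boron_physical_dose(10.0, BEAM, KERMA)
        assert d2 == pytest.approx(2.0 * d1)

    def test_arithmetic_oracle(self):
        # independent hand multiplication: c * (7.0e8 * 3600) * 10
        kerma = KermaSet(boron_coefficient=3.0e-14)
        expected = 3.0e-14 * 2.52e12 * 10.0
        assert boron_physical_dose(10.0, BEAM, kerma) == pytest.approx(expected, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            boron_physical_dose(-1.0, BEAM, KERMA)


class TestTotalPhysicalDose:
    def test_all_zero(self):
        assert total_physical_dose(DoseComponents(0, 0, 0, 0)) == 0.0

    def test_hand_sum_boron_free_beam(self):
        assert total_physical_dose(DoseComponents(0.0, 0.2, 0.15, 0.65)) == pytest.approx(1.0)

    def test_permutation_invariance(self):
        values = (0.3, 0.7, 1.1, 2.9)
        totals = [
            total_physical_dose(DoseComponents(*perm))
            for perm in itertools.permutations(values)
        ]
        assert max(totals) - min(totals) < 1e-12


class TestPhotonEquivalentDose:
    def test_identity_weights_equal_physical(self):
        comps = DoseComponents(1.2, 0.3, 0.4, 0.5)
        weights = WeightSet(cbe=1.0, rbe_n=1.0, rbe_h=1.0, cbe_brain=1.0)
        assert photon_equivalent_dose(comps, weights) == pytest.approx(
            total_physical_dose(comps)
        )

    def test_default_split_maps_one_gray_to_1p7(self):
        # boron-free 1.0 Gy with the shipped component split and RBE 3.0
        comps = beam_dose_components(0.0, BEAM, KERMA)
        assert total_physical_dose(comps) == pytest.approx(1.0, abs=1e-12)
        assert photon_equivalent_dose(comps, WeightSet(cbe=2.0)) == pytest.approx(
            1.7, abs=1e-9
        )

    def test_boron_on_top_of_beam_term(self):
        # D_B = 2.4 Gy weighted 2.02 stacked on the 1.7 Gy-Eq beam
        comps = DoseComponents(2.4, 0.175, 0.175, 0.65)
        gy_eq = photon_equivalent_dose(comps, WeightSet(cbe=2.02))
        assert gy_eq == pytest.approx(2.4 * 2.02 + 1.7, abs=1e-12)
        # lands within input-rounding distance of the published 6.7 Gy-Eq cell
        assert abs(gy_eq - 6.7) < 0.25

    def test_brain_flag_switches_weight(self):
        comps = DoseComponents(1.0, 0.0, 0.0, 0.0)
        weights = WeightSet(cbe=4.0, cbe_brain=1.35)
        assert photon_equivalent_dose(comps, weights, brain=True) == pytest.approx(1.35)

    @given(
        d=st.tuples(component_floats, component_floats, component_floats, component_floats),
        w=st.tuples(
            st.floats(1.0, 10.0), st.floats(1.0, 10.0), st.floats(1.0, 10.0)
        ),
    )
    @settings(max_examples=200)
    def test_weighted_at_least_physical_when_weights_geq_one(self, d, w):
        comps = DoseComponents(*d)
        weights = WeightSet(cbe=w[0], rbe_n=w[1], rbe_h=w[2])
        assert photon_equivalent_dose(comps, weights) >= total_physical_dose(comps) - 1e-12


class TestEffectiveBoronConcentration:
    def test_quarter_contribution(self):
        scenario = DoseScenario("tumor", boron_mean=45.8, boron_sd=16.5,
                                contribution_fraction=0.25)
        assert effective_boron_concentration(scenario, "mean") == pytest.approx(11.45)

    def test_identity_fraction(self):
        scenario = DoseScenario("tumor", boron_mean=17.8, boron_sd=1.4)
        assert effective_boron_concentration(scenario, "mean") == pytest.approx(17.8)

    def test_mean_minus_sd_floored_at_zero(self):
        scenario = DoseScenario("tumor", boron_mean=25.1, boron_sd=26.6,
                                contribution_fraction=0.25)
        assert effective_boron_concentration(scenario, "mean-sd") == 0.0

    def test_invalid_selector(self):
        with pytest.raises(InvalidInputError):
            effective_boron_concentration(DoseScenario("t", 1.0), "median")


class TestDoseReport:
    def test_empty_scenarios(self):
        table = dose_report([], BEAM, KERMA, WeightSet(cbe=2.0))
        assert table.empty

    def test_boron_free_scenario_reduces_to_beam_row(self):
        table = dose_report(
            [DoseScenario("beam-only", 0.0)], BEAM, KERMA, WeightSet(cbe=5.0)
        )
        assert np.allclose(table["physical_dose_gy"], 1.0)
        assert np.allclose(table["photon_equivalent_gy_eq"], 1.7)

    def test_mean_sd_ordering(self):
        table = dose_report(
            [DoseScenario("tumor", 45.8, 16.5, 0.25)], BEAM, KERMA, WeightSet(cbe=4.66)
        ).set_index("statistic")
        lo = table.loc["mean-sd", "photon_equivalent_gy_eq"]
        mid = table.loc["mean", "photon_equivalent_gy_eq"]
        hi = table.loc["mean+sd", "photon_equivalent_gy_eq"]
        assert lo <= mid <= hi

    def test_duration_homogeneity_degree_one(self):
        scenario = DoseScenario("tumor", 20.0, 5.0)
        short = dose_report([scenario], BEAM, KERMA, WeightSet(cbe=2.0))
        double = BeamSpec(BEAM.flux, BEAM.duration * 2, BEAM.nonboron_dose_rate,
                          BEAM.component_split)
        long = dose_report([scenario], double, KERMA, WeightSet(cbe=2.0))
        for column in ("physical_dose_gy", "photon_equivalent_gy_eq", "d_boron_gy"):
            assert np.allclose(long[column], 2.0 * short[column])

    def test_brain_rows_use_brain_weight(self):
        weights = WeightSet(cbe=4.66, cbe_brain=1.35)
        table = dose_report(
            [
                DoseScenario("tumor", 10.0, 0.0, compound="X"),
                DoseScenario("brain", 10.0, 0.0, compound="X", use_brain_cbe=True),
            ],
            BEAM,
            KERMA,
            {"X": weights},
        )
        by_tissue = table.groupby("tissue")["photon_equivalent_gy_eq"].first()
        assert by_tissue["brain"] < by_tissue["tumor"]
        assert set(table.loc[table["tissue"] == "brain", "cbe_used"]) == {1.35}

    def test_missing_compound_weight_errors(self):
        with pytest.raises(ConfigurationError):
            dose_report(
                [DoseScenario("tumor", 10.0, compound="unknown")],
                BEAM,
                KERMA,
                {"X": WeightSet(cbe=2.0)},
            )


class TestValidation:
    def test_split_must_sum_to_one(self):
        with pytest.raises(InvalidInputError):
            BeamSpec(1e8, 60.0, 1e-4, component_split=(0.3, 0.3, 0.3))

    def test_negative_component_rejected(self):
        with pytest.raises(InvalidInputError):
            DoseComponents(-0.1, 0, 0, 0)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(InvalidInputError):
            WeightSet(cbe=0.0)

    def test_contribution_fraction_range(self):
        with pytest.raises(InvalidInputError):
            DoseScenario("t", 1.0, contribution_fraction=0.0)
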