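"""Decay scenarios: label dilution, corrected yields, heterotrophic share."""

import numpy as np
import pytest

from isoyield.decay import (
    DEFAULT_DIC_MG_C_PER_L,
    DecayScenario,
    corrected_yield,
    heterotrophic_contribution,
    heterotrophic_contribution_range,
    medium_dilution_series,
    scenario_for_temperature,
)
from isoyield.errors import ConfigError, DegenerateMixingError
from isoyield.regression import estimate_yield
from isoyield.simulate import make_fixture_suite

from conftest import make_replicate


def test_dic_pool_from_medium_recipe():
    # 0.5 g NaHCO3 per litre carries ~71.5 mg of carbon
    assert DEFAULT_DIC_MG_C_PER_L == pytest.approx(71.5, abs=0.1)


def test_fraction_split_must_sum_to_one():
    with pytest.raises(ValueError):
        DecayScenario(kind="all_to_co2", particulate_fraction=0.2,
                      biodegradable_fraction=0.92)


class TestMediumDilution:
    def test_zero_decay_leaves_label_pure(self):
        rep = make_replicate([0.011, 0.02, 0.03], times=[0, 4, 8])
        scen = DecayScenario(kind="all_to_co2", decay_rate=0.0)
        res = medium_dilution_series(rep, scen)
        np.testing.assert_allclose(res.a_medium_series, 0.99)

    def test_carbon_weighted_mean_single_interval(self):
        """One interval's dilution matches the closed-form weighted mean."""
        # 636 mg C/L of biomass at natural abundance, 13 % decays into a
        # 71.4 mg C/L pool at 0.99 purity
        vss0 = 636.0 / (1000.0 * 0.531)
        b = -24.0 * np.log(1.0 - 0.13)  # 13 % decayed over 1 h
        rep = make_replicate([0.011, 0.011], times=[0.0, 1.0], vss0=vss0)
        scen = DecayScenario(kind="all_to_co2", decay_rate=b, dic_pool=71.4)
        res = medium_dilution_series(rep, scen)
        expected = (0.99 * 71.4 + 0.011 * 82.68) / (71.4 + 82.68)
        assert res.pool_abundance == pytest.approx(expected, rel=1e-6)
        # interval 0 itself still sees the undiluted pool
        assert res.a_medium_series[0] == pytest.approx(0.99)

    def test_death_regeneration_limit_no_respiration(self):
        """het_yield -> 1 with no particulate retention respires nothing."""
        rep = make_replicate([0.011, 0.02, 0.03], times=[0, 4, 8])
        scen = DecayScenario(
            kind="death_regeneration", decay_rate=0.5, het_yield=1.0 - 1e-12,
            particulate_fraction=0.0, biodegradable_fraction=1.0,
        )
        res = medium_dilution_series(rep, scen)
        np.testing.assert_allclose(res.a_medium_series, 0.99, rtol=1e-9)

    def test_carbon_conservation(self):
        """Decayed carbon = respired into DIC + retained, exactly."""
        rep = make_replicate([0.011, 0.02, 0.04, 0.05], times=[0, 4, 8, 12])
        scen = scenario_for_temperature(28.0, "death_regeneration")
        res = medium_dilution_series(rep, scen, substeps=4)
        assert res.respired_carbon + res.retained_carbon == pytest.approx(
            res.decayed_carbon, rel=1e-12
        )
        assert res.pool_mass == pytest.approx(
            res.initial_pool_mass + res.respired_carbon, rel=1e-9
        )

    def test_substep_refinement_converges(self):
        rep = make_replicate([0.011, 0.03, 0.05], times=[0, 6, 12])
        scen = DecayScenario(kind="all_to_co2", decay_rate=0.4)
        coarse = medium_dilution_series(rep, scen, substeps=1)
        mid = medium_dilution_series(rep, scen, substeps=32)
        fine = medium_dilution_series(rep, scen, substeps=64)
        assert fine.pool_abundance == pytest.approx(
            coarse.pool_abundance, rel=0.05
        )
        # refinement converges: successive halvings agree far better than
        # the single-step bookkeeping does
        assert abs(fine.pool_abundance - mid.pool_abundance) < 0.05 * abs(
            fine.pool_abundance - coarse.pool_abundance
        )

    def test_requires_active_scenario(self):
        rep = make_replicate([0.011, 0.02], times=[0, 4])
        with pytest.raises(ConfigError):
            medium_dilution_series(rep, DecayScenario(kind="none"))


class TestCorrectedYield:
    def test_none_scenario_is_uncorrected(self):
        bundle = make_fixture_suite("meso28", seed=5)
        reps = bundle.ammonium_replicates
        est = corrected_yield(reps, DecayScenario(kind="none"))
        assert est.y_max == pytest.approx(estimate_yield(reps).y_max, rel=1e-12)

    @pytest.mark.parametrize("preset, temp", [
        ("meso15", 15.0), ("meso28", 28.0), ("thermo50", 50.0),
    ])
    def test_scenario_ordering(self, preset, temp):
        """as-such <= death-regeneration <= all-to-CO2 on every dataset."""
        bundle = make_fixture_suite(preset, seed=11)
        for reps in (bundle.ammonium_replicates, bundle.nitrite_replicates):
            as_such = estimate_yield(reps).y_max
            dr = corrected_yield(
                reps, scenario_for_temperature(temp, "death_regeneration")
            ).y_max
            co2 = corrected_yield(
                reps, scenario_for_temperature(temp, "all_to_co2")
            ).y_max
            assert as_such <= dr <= co2

    def test_correction_vanishes_as_decay_vanishes(self):
        bundle = make_fixture_suite("meso15", seed=2)
        reps = bundle.ammonium_replicates
        base = estimate_yield(reps).y_max
        tiny = DecayScenario(kind="all_to_co2", decay_rate=1e-8)
        corrected = corrected_yield(reps, tiny).y_max
        assert abs(corrected - base) / base <= 1e-4

    def test_matched_correction_reduces_bias(self):
        """Simulating with decay and correcting with the matching scenario
        recovers Y_max more accurately than the uncorrected estimate."""
        scen = scenario_for_temperature(15.0, "death_regeneration")
        err_unc, err_cor = [], []
        for seed in range(100):
            bundle = make_fixture_suite(
                "meso15", seed=seed, decay_rate=scen.decay_rate,
                smp_het_fraction=1.0 - scen.respired_share,
            )
            reps = bundle.ammonium_replicates
            truth = bundle.true_total_yield
            err_unc.append(abs(estimate_yield(reps).y_max - truth))
            err_cor.append(abs(corrected_yield(reps, scen).y_max - truth))
        assert np.mean(err_cor) < np.mean(err_unc)

    def test_extreme_dilution_is_degenerate(self):
        rep = make_replicate([0.011, 0.5, 0.9], times=[0, 4, 8])
        scen = DecayScenario(kind="all_to_co2", decay_rate=50.0, dic_pool=1.0)
        with pytest.raises(DegenerateMixingError):
            corrected_yield([rep], scen)

    def test_endpoint_mode_corrects_at_least_as_much(self):
        bundle = make_fixture_suite("meso15", seed=4)
        reps = bundle.ammonium_replicates
        scen = scenario_for_temperature(15.0, "all_to_co2")
        per_interval = corrected_yield(reps, scen).y_max
        endpoint = corrected_yield(reps, scen, endpoint_only=True).y_max
        assert endpoint >= per_interval


class TestHeterotrophicContribution:
    def test_zero_decay_or_yield_contributes_nothing(self):
        bundle = make_fixture_suite("thermo50", noiseless=True, n_replicates=1)
        rep = bundle.ammonium_replicates[0]
        assert heterotrophic_contribution(rep, 0.0, 0.75) == 0.0
        assert heterotrophic_contribution(rep, 0.05, 0.0) == 0.0

    def test_subpercent_at_nitrifier_decay_rates(self):
        """At the low nitrifier decay rates and a 4 h incubation the
        heterotrophic share of labelled biomass is a few tenths of a
        percent."""
        bundle = make_fixture_suite("thermo50", noiseless=True, n_replicates=1)
        rep = bundle.ammonium_replicates[0]
        lo, hi = heterotrophic_contribution_range(rep, (0.03, 0.06), 0.75)
        assert 0.0 < lo < hi < 0.01
        assert 0.0005 < lo  # order 0.1 %, not 0.01 %
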