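"""Yield fitting, aggregation, guild subtraction, and vss0 sensitivity."""

import numpy as np
import pytest

from isoyield.errors import (
    InsufficientDataError,
    InvalidPerturbationError,
    PairingError,
    UndefinedSlopeError,
)
from isoyield.isotope import ChemTimePoint, biomass_trajectory
from isoyield.regression import (
    YieldEstimate,
    aggregate_replicates,
    estimate_yield,
    fit_replicate_yield,
    sensitivity_initial_biomass,
    subtract_nob,
)
from isoyield.simulate import SimulationConfig, make_fixture_suite, simulate_incubation

from conftest import make_replicate


def noiseless_config(**kw):
    base = dict(
        true_yield=0.10,
        oxidation_rate=10.0,
        sampling_times=[0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
        irms_sd=0.0,
        vss0_rel_error_sd=0.0,
        n_sd=0.0,
        n_replicates=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestFitReplicateYield:
    def test_recovers_true_yield_from_noiseless_simulation(self):
        sim = simulate_incubation(noiseless_config())[0]
        rep = sim.replicate
        fit = fit_replicate_yield(
            biomass_trajectory(rep), rep.chem_series, "ammonium"
        )
        assert fit.slope == pytest.approx(0.10, rel=1e-8)
        assert fit.r_squared >= 0.9999

    def test_constant_vss_gives_zero_slope(self):
        rep = make_replicate([0.011] * 4, nh4=[50, 40, 30, 20])
        fit = fit_replicate_yield(
            biomass_trajectory(rep), rep.chem_series, "ammonium"
        )
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_no_consumption_is_undefined(self):
        rep = make_replicate([0.011, 0.02], nh4=[50, 50])
        with pytest.raises(UndefinedSlopeError):
            fit_replicate_yield(
                biomass_trajectory(rep), rep.chem_series, "ammonium"
            )

    def test_chemistry_interpolated_onto_isotope_grid(self):
        """A sparser chemistry grid is linearly interpolated and flagged."""
        sim = simulate_incubation(noiseless_config())[0]
        rep = sim.replicate
        # drop interior measurements (keep the endpoints so the isotope
        # grid stays inside the chemistry grid)
        sparse_chem = [rep.chem_series[i] for i in (0, 2, 5)]
        fit = fit_replicate_yield(
            biomass_trajectory(rep), sparse_chem, "ammonium"
        )
        # substrate declines linearly, so interpolation is exact here
        assert fit.slope == pytest.approx(0.10, rel=1e-8)
        assert fit.interpolated

    def test_too_few_chemistry_points(self):
        sim = simulate_incubation(noiseless_config())[0]
        rep = sim.replicate
        with pytest.raises(InsufficientDataError):
            fit_replicate_yield(
                biomass_trajectory(rep), [ChemTimePoint(0.0, 50.0, 0.0)],
                "ammonium",
            )

    def test_through_origin_matches_on_interceptless_data(self):
        sim = simulate_incubation(noiseless_config())[0]
        rep = sim.replicate
        fit = fit_replicate_yield(
            biomass_trajectory(rep), rep.chem_series, "ammonium",
            through_origin=True,
        )
        assert fit.slope == pytest.approx(0.10, rel=1e-8)


class TestAggregateAndSubtract:
    @pytest.mark.parametrize(
        "slopes, mean, sd",
        [
            ([0.1, 0.1, 0.1], 0.1, 0.0),
            ([0.2, 0.22, 0.24], 0.22, 0.02),
            ([0.05], 0.05, 0.0),
        ],
    )
    def test_mean_and_sample_sd(self, slopes, mean, sd):
        est = aggregate_replicates(
            slopes, guild="total_nitrifier", substrate="ammonium",
            temperature=28.0,
        )
        assert est.y_max == pytest.approx(mean, abs=1e-12)
        assert est.sd == pytest.approx(sd, abs=1e-12)
        assert est.n_replicates == len(slopes)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            aggregate_replicates(
                [], guild="nob", substrate="nitrite", temperature=28.0
            )

    def _est(self, y, sd, substrate, guild, temperature=50.0):
        return YieldEstimate(
            y_max=y, sd=sd, n_replicates=3, r_squared=0.99, guild=guild,
            substrate=substrate, temperature=temperature,
        )

    def test_ammonia_oxidizer_by_subtraction(self):
        total = self._est(0.245, 0.04, "ammonium", "total_nitrifier")
        nob = self._est(0.025, 0.002, "nitrite", "nob")
        aoboa = subtract_nob(total, nob)
        assert aoboa.y_max == pytest.approx(0.22, abs=1e-12)
        assert aoboa.guild == "aoboa"
        assert aoboa.sd == pytest.approx(np.hypot(0.04, 0.002), rel=1e-12)
        # subtraction is exact: adding the NOB yield back restores the total
        assert aoboa.y_max + nob.y_max == total.y_max

    def test_subtraction_15c_study_values(self):
        total = self._est(0.161, 0.01, "ammonium", "total_nitrifier", 15.0)
        nob = self._est(0.051, 0.002, "nitrite", "nob", 15.0)
        assert subtract_nob(total, nob).y_max == pytest.approx(0.110, abs=1e-12)

    def test_zero_nob_leaves_total(self):
        total = self._est(0.2, 0.01, "ammonium", "total_nitrifier")
        nob = self._est(0.0, 0.0, "nitrite", "nob")
        assert subtract_nob(total, nob).y_max == total.y_max

    def test_mismatched_conditions_rejected(self):
        total = self._est(0.2, 0.01, "ammonium", "total_nitrifier", 50.0)
        nob = self._est(0.05, 0.0, "nitrite", "nob", 15.0)
        with pytest.raises(PairingError):
            subtract_nob(total, nob)
        with pytest.raises(PairingError):
            subtract_nob(nob, nob)

    def test_negative_difference_warns_not_clamps(self):
        total = self._est(0.02, 0.01, "ammonium", "total_nitrifier")
        nob = self._est(0.05, 0.002, "nitrite", "nob")
        with pytest.warns(UserWarning):
            est = subtract_nob(total, nob)
        assert est.y_max == pytest.approx(-0.03)


class TestSensitivity:
    def test_identity_factor_is_baseline(self):
        bundle = make_fixture_suite("thermo50", noiseless=True)
        reps = bundle.ammonium_replicates
        baseline = estimate_yield(reps)
        table = sensitivity_initial_biomass(reps, [1.0])
        assert table[1.0].y_max == pytest.approx(baseline.y_max, rel=1e-12)

    def test_exact_homogeneity_in_vss0(self):
        """The inversion is linear in vss0, so Y_max scales exactly."""
        bundle = make_fixture_suite("meso28", noiseless=True)
        reps = bundle.ammonium_replicates
        table = sensitivity_initial_biomass(reps, [0.9, 1.0, 1.1])
        base = table[1.0].y_max
        assert table[0.9].y_max == pytest.approx(0.9 * base, rel=1e-10)
        assert table[1.1].y_max == pytest.approx(1.1 * base, rel=1e-10)

    def test_nonpositive_factor_rejected(self):
        bundle = make_fixture_suite("thermo50", noiseless=True, n_replicates=1)
        with pytest.raises(InvalidPerturbationError):
            sensitivity_initial_biomass(bundle.ammonium_replicates, [0.0])


def test_estimate_yield_rejects_mixed_conditions():
    b50 = make_fixture_suite("thermo50", noiseless=True, n_replicates=1)
    b15 = make_fixture_suite("meso15", noiseless=True, n_replicates=1)
    with pytest.raises(PairingError):
        estimate_yield(
            b50.ammonium_replicates + b15.ammonium_replicates
        )
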