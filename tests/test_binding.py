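"""Closed-form kinetic and equilibrium expressions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from znfbind.binding import (
    NM,
    NO_DISSOCIATION,
    ExponentialCurve,
    KineticSummary,
    RateConstants,
    association_curve,
    dissociation_curve,
    dissociation_halftime,
    equilibration_halftime,
    equilibrium_constant,
    fraction_bound_depletion,
    fraction_bound_simple,
    observed_rate,
    propagate_kd_error,
)

rate_values = st.floats(min_value=1e-2, max_value=1e8)
koff_values = st.floats(min_value=0.0, max_value=1.0)
conc_values = st.floats(min_value=0.0, max_value=1e-3)


class TestRateConstants:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            RateConstants(k_on=0.0, k_off=1e-5)
        with pytest.raises(ValueError):
            RateConstants(k_on=100.0, k_off=-1e-5)
        with pytest.raises(ValueError):
            RateConstants(k_on=100.0, k_off=1e-5, dk_on=-1.0)

    def test_exponential_curve_requires_positive_tau(self):
        with pytest.raises(ValueError):
            ExponentialCurve(y0=0.0, A=1.0, tau=-5.0)


class TestObservedRate:
    @pytest.mark.parametrize(
        "c_nM, k_on, k_off, expected",
        [
            (0.0, 725.0, 1.1e-5, 1.1e-5),
            (625.0, 725.0, 1.1e-5, 4.64125e-4),
            (1250.0, 135.0, 2.2e-5, 1.9075e-4),
        ],
    )
    def test_values(self, c_nM, k_on, k_off, expected):
        rates = RateConstants(k_on=k_on, k_off=k_off)
        assert observed_rate(c_nM * NM, rates) == pytest.approx(expected, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            observed_rate(-1e-9, RateConstants(k_on=100.0, k_off=0.0))

    @given(k_on=rate_values, k_off=koff_values, c=conc_values, dc=conc_values)
    @settings(max_examples=50, derandomize=True)
    def test_strictly_increasing_in_concentration(self, k_on, k_off, c, dc):
        rates = RateConstants(k_on=k_on, k_off=k_off)
        assert observed_rate(c + dc + 1e-12, rates) > observed_rate(c, rates)

    def test_affine_in_concentration(self, measured_rates):
        """Regression over any >=2 concentrations recovers slope k_on and
        intercept k_off exactly."""
        c = np.array([78.0, 156.0, 312.0, 625.0, 1250.0]) * NM
        k = np.array([observed_rate(ci, measured_rates) for ci in c])
        slope, intercept = np.polyfit(c, k, 1)
        assert slope == pytest.approx(measured_rates.k_on, rel=1e-9)
        assert intercept == pytest.approx(measured_rates.k_off, rel=1e-6)


class TestDerivedQuantities:
    def test_equilibrium_constant_matches_reported_affinity(self):
        # fastest-association measurement: printed affinity 7.2 +/- 0.8 nM
        rates = RateConstants(k_on=1908.0, k_off=1.4e-5)
        assert equilibrium_constant(rates) / NM == pytest.approx(7.2, abs=0.2)

    def test_equilibrium_constant_arithmetic(self):
        assert equilibrium_constant(RateConstants(100.0, 1e-6)) == pytest.approx(1e-8)
        assert equilibrium_constant(RateConstants(100.0, 0.0)) == 0.0

    def test_error_propagation_matches_reported_value(self):
        # printed 15.7 +/- 4.1 nM from k_on=725+/-35, k_off=(1.1+/-0.3)e-5
        rates = RateConstants(725.0, 1.1e-5, dk_on=35.0, dk_off=0.3e-5)
        assert propagate_kd_error(rates) / NM == pytest.approx(4.1, abs=0.2)

    def test_error_propagation_formula(self):
        rates = RateConstants(1908.0, 1.4e-5, dk_on=130.0, dk_off=0.1e-5)
        expected = math.sqrt((0.1e-5 / 1908) ** 2 + (1.4e-5 * 130 / 1908**2) ** 2)
        assert propagate_kd_error(rates) == pytest.approx(expected, rel=1e-12)
        assert propagate_kd_error(RateConstants(100.0, 1e-5)) == 0.0

    @pytest.mark.parametrize(
        "k_off, hours",
        [(2.2e-5, 8.75), (1.1e-5, 17.5), (1.4e-5, 13.75), (math.log(2.0), 1 / 3600)],
    )
    def test_dissociation_halftime(self, k_off, hours):
        rates = RateConstants(100.0, k_off)
        assert dissociation_halftime(rates) / 3600 == pytest.approx(hours, rel=2e-3)

    def test_halftime_sentinel_for_irreversible_complex(self):
        assert dissociation_halftime(RateConstants(100.0, 0.0)) == NO_DISSOCIATION

    def test_equilibration_halftime(self):
        rates = RateConstants(725.0, 1.1e-5)
        assert equilibration_halftime(0.0, rates) == pytest.approx(
            dissociation_halftime(rates)
        )
        assert equilibration_halftime(2284.0 * NM, rates) == pytest.approx(416, rel=0.01)
        # ~10x the halftime at the lowest titration-relevant concentration is
        # the ~90 h equilibrium incubation
        t10 = 10 * equilibration_halftime(14.3 * NM, rates)
        assert t10 / 3600 == pytest.approx(90, rel=0.03)

    def test_summary_consistency(self, measured_rates):
        s = KineticSummary.from_rates(measured_rates)
        assert s.K_D == equilibrium_constant(measured_rates)
        assert s.t_half_off == dissociation_halftime(measured_rates)
        assert s.dK_D >= 0


class TestCurves:
    def test_association_start_efold_asymptote(self):
        rates = RateConstants(725.0, 1.1e-5)
        curve = ExponentialCurve(y0=60.0, A=40.0, x0=10.0)
        c = 625 * NM
        assert association_curve(10.0, c, rates, curve) == pytest.approx(100.0)
        t_e = 10.0 + 1.0 / observed_rate(c, rates)
        assert association_curve(t_e, c, rates, curve) == pytest.approx(60 + 40 / math.e)
        assert association_curve(1e9, c, rates, curve) == pytest.approx(60.0)

    def test_dissociation_halftime_point(self):
        tau = 1 / 2.2e-5
        curve = ExponentialCurve(y0=50.0, A=40.0, x0=0.0, tau=tau)
        assert dissociation_curve(0.0, curve) == pytest.approx(90.0)
        assert dissociation_curve(tau * math.log(2), curve) == pytest.approx(70.0)
        assert dissociation_curve(31507.0, curve) == pytest.approx(70.0, rel=1e-4)

    def test_same_exponential_family(self):
        """Association at rate k_obs equals dissociation at tau = 1/k_obs."""
        rates = RateConstants(725.0, 1.1e-5)
        c = 312 * NM
        k_obs = observed_rate(c, rates)
        t = np.linspace(0, 5000, 50)
        a = association_curve(t, c, rates, ExponentialCurve(30.0, 70.0))
        d = dissociation_curve(t, ExponentialCurve(30.0, 70.0, tau=1 / k_obs))
        np.testing.assert_allclose(a, d, rtol=1e-12)


class TestIsotherms:
    def test_half_bound_at_kd(self):
        assert fraction_bound_simple(25 * NM, 25 * NM) == 50.0
        assert fraction_bound_simple(0.0, 25 * NM) == 0.0
        assert fraction_bound_simple(75 * NM, 25 * NM) == pytest.approx(75.0)

    def test_depletion_example(self):
        st_ = fraction_bound_depletion(25 * NM, 3 * NM, 25 * NM)
        assert st_.C / NM == pytest.approx(1.455, rel=1e-3)
        assert st_.fraction_bound == pytest.approx(48.5, rel=1e-3)

    def test_depletion_reduces_to_simple_isotherm(self):
        for R_nM in (1.0, 25.0, 400.0):
            deplete = fraction_bound_depletion(R_nM * NM, 25e-9 * NM, 25 * NM)
            assert deplete.fraction_bound == pytest.approx(
                fraction_bound_simple(R_nM * NM, 25 * NM), abs=1e-6
            )

    def test_infinitely_tight_binding(self):
        assert fraction_bound_depletion(10 * NM, 3 * NM, 0.0).fraction_bound == 100.0
        # limiting protein: all protein in complex
        assert fraction_bound_depletion(2 * NM, 3 * NM, 0.0).C == pytest.approx(2 * NM)

    @given(
        R=st.floats(min_value=0, max_value=1e-5),
        dR=st.floats(min_value=1e-12, max_value=1e-5),
        L=st.floats(min_value=1e-12, max_value=1e-6),
        K=st.floats(min_value=1e-12, max_value=1e-5),
        dK=st.floats(min_value=1e-12, max_value=1e-5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_depletion_monotone(self, R, dR, L, K, dK):
        """Bound fraction grows with receptor and shrinks with K_D."""
        f = fraction_bound_depletion(R, L, K).fraction_bound
        assert fraction_bound_depletion(R + dR, L, K).fraction_bound >= f - 1e-9
        assert fraction_bound_depletion(R, L, K + dK).fraction_bound <= f + 1e-9

    @given(
        R=st.floats(min_value=0, max_value=1e-5),
        L=st.floats(min_value=1e-12, max_value=1e-6),
        K=st.floats(min_value=0, max_value=1e-5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_depletion_respects_mass_limits(self, R, L, K):
        st_ = fraction_bound_depletion(R, L, K)
        assert 0.0 <= st_.C <= min(R, L) * (1 + 1e-12) + 1e-30
        assert 0.0 <= st_.fraction_bound <= 100.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fraction_bound_simple(1e-9, 0.0)
        with pytest.raises(ValueError):
            fraction_bound_depletion(1e-9, 0.0, 1e-9)
        with pytest.raises(ValueError):
            fraction_bound_depletion(-1e-9, 1e-9, 1e-9)
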