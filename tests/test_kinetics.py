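"""Unit and property tests for the 0D conjugation kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from adcscale.kinetics import (
    ALL_ACTIVATED,
    NOT_REACHED,
    ActivationDistribution,
    FeedSchedule,
    KineticParameters,
    SpeciesState,
    completion_time,
    dar,
    initial_state,
    molar_from_mass,
    payload_volume_fraction,
    reaction_rates,
    simulate_0d,
)


@pytest.mark.parametrize(
    "mass, molar_mass, expected",
    [(0.0, 150000.0, 0.0), (5.0, 150000.0, 0.0333333), (10.0, 150000.0, 0.0666667)],
)
def test_molar_from_mass(mass, molar_mass, expected):
    assert molar_from_mass(mass, molar_mass) == pytest.approx(expected, rel=1e-4)


def test_molar_from_mass_rejects_bad_molar_mass():
    with pytest.raises(ValueError):
        molar_from_mass(5.0, 0.0)


def test_payload_volume_fraction_standard_condition():
    """5x excess over 0.0333 mM antibody from a 10 mM stock is 1.67% v/v."""
    total = 5.0 * molar_from_mass(5.0, 150000.0)
    assert payload_volume_fraction(total, 10.0) == pytest.approx(1.6667, abs=5e-4)


class TestReactionRates:
    def test_no_drug_no_reaction(self, default_params):
        state = SpeciesState(A2=0.03, A1=0.01, A0=0.002, M1a=0.005, D=0.0)
        rates = reaction_rates(state, default_params)
        assert all(getattr(rates, s) == 0.0 for s in ("A2", "A1", "M1a", "M2", "D"))

    def test_first_conjugation_step_hand_value(self):
        state = SpeciesState(A2=0.0333, D=0.1667)
        rates = reaction_rates(state, KineticParameters(k1=0.797))
        assert rates.A2 == pytest.approx(-4.424e-3, rel=1e-3)

    def test_drug_sink_only(self):
        state = SpeciesState(D=1.0)
        rates = reaction_rates(state, KineticParameters(k3=0.00155))
        assert rates.D == pytest.approx(-0.00155)
        assert rates.Dinact == pytest.approx(0.00155)

    def test_mab_derivatives_sum_to_zero(self, default_params):
        state = SpeciesState(A2=0.02, A1=0.005, A0=0.001, M1a=0.004, M1b=0.002, M2=0.01, D=0.08)
        r = reaction_rates(state, default_params)
        assert r.A2 + r.A1 + r.A0 + r.M1a + r.M1b + r.M2 == pytest.approx(0.0, abs=1e-18)

    def test_negative_concentration_rejected(self, default_params):
        with pytest.raises(ValueError):
            reaction_rates(SpeciesState(A2=-0.01, D=0.1), default_params)


class TestDar:
    def test_zero_conjugate(self):
        assert dar(SpeciesState(A2=0.03), 0.03) == 0.0

    def test_full_biconjugation_gives_two(self):
        assert dar(SpeciesState(M2=0.03), 0.03) == pytest.approx(2.0)

    def test_full_conversion_with_distribution(self):
        """Complete conversion of all activated sites: DAR = 2 p2 + p1."""
        d = ActivationDistribution()
        c0 = 1.0
        state = SpeciesState(A0=d.p0, M1b=d.p1, M2=d.p2)
        assert dar(state, c0) == pytest.approx(1.8578, abs=1e-4)

    def test_zero_initial_mab_rejected(self):
        with pytest.raises(ValueError):
            dar(SpeciesState(), 0.0)


class TestSimulate0d:
    def test_zero_payload_is_inert(self, default_params, default_distribution):
        init = initial_state(0.0333, default_distribution)
        feed = FeedSchedule.batch(0.0)
        traj = simulate_0d(init, default_params, feed, 100.0, 1.0)
        assert np.allclose(traj.states, traj.states[0])
        assert np.all(traj.dar == 0.0)
        assert completion_time(traj, 0.01) == NOT_REACHED

    def test_pseudo_first_order_limit(self):
        """With k2 = k3 = 0 and 50x payload excess, A2 decays almost exactly
        exponentially during the rise phase (payload depletion <= 2%)."""
        params = KineticParameters(k1=0.797, k2=0.0, k3=0.0)
        c_mab0, excess = 0.02, 50.0
        d0 = excess * c_mab0
        lam = params.k1 * d0
        t_end = 0.5 / lam
        init = initial_state(c_mab0, ALL_ACTIVATED)
        traj = simulate_0d(init, params, FeedSchedule.batch(d0), t_end, t_end / 50)
        expected = init.A2 * np.exp(-lam * traj.times)
        assert np.max(np.abs(traj.species("A2") - expected) / expected) < 0.005

    def test_mab_conservation_and_drug_balance(self, standard_trajectory):
        assert standard_trajectory.mab_conservation_error() < 1e-6
        assert standard_trajectory.drug_balance_error() < 1e-6

    def test_dar_monotone_nondecreasing(self, standard_trajectory):
        assert np.all(np.diff(standard_trajectory.dar) >= -1e-9)
        assert np.all(standard_trajectory.dar <= 2.0 + 1e-9)

    def test_distribution_reduction_to_three_reaction_model(self, default_params):
        """With p2 = 1 the activation-distribution variant collapses onto the
        plain three-reaction scheme, checked against an independently coded
        4-species oracle integrated with the same solver settings."""
        c0, feed = 0.0333, FeedSchedule.batch(0.1667)
        traj = simulate_0d(initial_state(c0, ALL_ACTIVATED), default_params, feed, 200.0, 1.0)
        k1, k2, k3 = default_params.k1, default_params.k2, default_params.k3

        def oracle(t, y):
            mab, mono, bi, drug = y
            return [
                -k1 * mab * drug,
                k1 * mab * drug - k2 * mono * drug,
                k2 * mono * drug,
                -k1 * mab * drug - k2 * mono * drug - k3 * drug,
            ]

        sol = solve_ivp(
            oracle, (0, 200.0), [c0, 0.0, 0.0, 0.1667],
            t_eval=traj.times, method="LSODA", rtol=1e-8, atol=1e-10,
        )
        assert np.allclose(traj.species("A2"), sol.y[0], atol=1e-8)
        assert np.allclose(traj.species("M1a"), sol.y[1], atol=1e-8)
        assert np.allclose(traj.species("M2"), sol.y[2], atol=1e-8)
        assert np.allclose(traj.species("A1"), 0.0) and np.allclose(traj.species("M1b"), 0.0)

    def test_explicit_output_grid(self, default_params):
        grid = np.array([0.0, 1.0, 5.0, 20.0])
        traj = simulate_0d(
            initial_state(0.03, ALL_ACTIVATED), default_params,
            FeedSchedule.batch(0.15), 20.0, grid,
        )
        assert np.array_equal(traj.times, grid)


class TestCompletionTime:
    def test_standard_fed_batch_completes_within_300s(self, standard_trajectory):
        t = completion_time(standard_trajectory, 0.01)
        assert t <= 300.0

    def test_batch_10mg_completes_within_900s(self, default_params, default_distribution):
        c0 = molar_from_mass(10.0, 150000.0)
        init = initial_state(c0, default_distribution)
        traj = simulate_0d(init, default_params, FeedSchedule.batch(5.0 * c0), 900.0, 0.1)
        assert completion_time(traj, 0.01) <= 900.0

    def test_invalid_residual_fraction(self, standard_trajectory):
        with pytest.raises(ValueError):
            completion_time(standard_trajectory, 1.5)


class TestValidation:
    def test_negative_rate_constant_rejected(self):
        with pytest.raises(ValueError):
            KineticParameters(k1=-1.0)

    def test_distribution_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ActivationDistribution(p2=0.5, p1=0.5, p0=0.5)

    def test_batch_mode_requires_zero_duration(self):
        with pytest.raises(ValueError):
            FeedSchedule("batch-instant", 10.0, 0.1)


@settings(max_examples=30, deadline=None)
@given(
    p2=st.floats(0.0, 1.0),
    split=st.floats(0.0, 1.0),
    c0=st.floats(1e-4, 1.0),
)
def test_max_dar_bounded_by_distribution(p2, split, c0):
    """Full conversion of any activation distribution never exceeds DAR 2."""
    p1 = (1.0 - p2) * split
    p0 = max(0.0, 1.0 - p2 - p1)
    d = ActivationDistribution(p2=p2, p1=p1, p0=p0)
    state = SpeciesState(A0=d.p0 * c0, M1b=d.p1 * c0, M2=d.p2 * c0)
    assert 0.0 <= dar(state, c0) <= 2.0 + 1e-12
    assert dar(state, c0) == pytest.approx(d.max_dar, rel=1e-12)
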