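"""Two-state channel model: thermodynamics, equilibrium sigmoid, gating
kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from fracgate import (
    ChannelParams,
    UniformGrid,
    config_entropy,
    equilibrium_open_probability,
    free_energy,
    open_probability_drift,
    simulate_channel,
)
from fracgate.channel import channel_landscape, step_voltage
from fracgate.errors import DomainError


class TestConfigEntropy:
    def test_symmetric_maximum_is_ln_two(self):
        assert config_entropy(0.5, n=1) == pytest.approx(math.log(2), rel=1e-12)

    def test_boundary_limit_vanishes(self):
        assert config_entropy(1e-15, n=1) == pytest.approx(0.0, abs=1e-12)

    def test_direct_arithmetic_value(self):
        expected = -4 * (0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert config_entropy(0.25, n=4) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.2493, abs=5e-5)

    def test_domain(self):
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(DomainError):
                config_entropy(bad)


class TestFreeEnergy:
    def test_pure_entropy_case(self):
        p = ChannelParams(n=1, eps1=0.0, eps2=0.0, z=1, beta=2.0, V=0.0)
        assert free_energy(0.5, p) == pytest.approx(-math.log(2) / 2.0, rel=1e-12)

    def test_entropy_term_symmetry(self):
        p = ChannelParams(n=3, eps1=0.0, eps2=0.0, z=1, beta=1.0, V=0.0)
        for x in (0.1, 0.25, 0.4):
            assert free_energy(x, p) == pytest.approx(free_energy(1 - x, p), rel=1e-12)

    def test_term_by_term_arithmetic(self):
        # independent term-by-term evaluation of the energy, electrical
        # work and entropy contributions
        p = ChannelParams(n=2, eps1=1.0, eps2=3.0, z=1, e0=1.0, beta=1.0, V=0.5)
        x = 0.3
        energy = 2 * (0.7 * 1.0 + 0.3 * 3.0)
        electrical = 1 * 1.0 * 2 * 0.7 * 0.5
        entropy = -2 * (0.7 * math.log(0.7) + 0.3 * math.log(0.3))
        assert free_energy(x, p) == pytest.approx(
            energy + electrical - entropy, rel=1e-12
        )

    def test_gradient_matches_central_difference(self, channel_params):
        channel_landscape(channel_params).validate_gradient()


class TestEquilibriumSigmoid:
    def test_exactly_half_open_at_threshold(self):
        for beta in (0.5, 1.0, 4.0):
            for z in (1, 2, 3):
                for e0 in (0.5, 1.0):
                    p = ChannelParams(n=5, eps1=-1.0, eps2=2.0, z=z,
                                      beta=beta, V=0.0, e0=e0)
                    assert equilibrium_open_probability(p.at_voltage(p.V0)) == 0.5

    def test_logit_three_gives_three_quarters(self):
        # β z e₀ (V − V₀) = ln 3 → P₀ = 1/(1 + 1/3)
        p = ChannelParams(n=1, eps1=0.0, eps2=0.0, z=1, beta=1.0, V=math.log(3))
        assert equilibrium_open_probability(p) == pytest.approx(0.75, rel=1e-14)

    def test_saturation_at_strong_depolarization(self):
        p = ChannelParams(n=1, eps1=0.0, eps2=0.0, z=1, beta=1.0, V=50.0)
        assert equilibrium_open_probability(p) == pytest.approx(1.0, abs=1e-20)

    def test_strictly_increasing_in_voltage(self):
        vs = np.linspace(-5, 5, 41)
        p = ChannelParams(n=1, eps1=0.2, eps2=-0.4, z=2, beta=1.3, V=0.0)
        vals = [equilibrium_open_probability(p.at_voltage(v)) for v in vs]
        assert np.all(np.diff(vals) > 0)
        assert all(0 < v < 1 for v in vals)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        beta=st.floats(0.1, 5.0),
        z=st.integers(1, 4),
        dv=st.floats(-6.0, 6.0),
    )
    def test_sigmoid_matches_boltzmann_closed_form(self, beta, z, dv):
        p = ChannelParams(n=2, eps1=0.0, eps2=0.0, z=z, beta=beta, V=dv)
        expected = 1.0 / (1.0 + math.exp(-beta * z * dv))
        assert equilibrium_open_probability(p) == pytest.approx(expected, rel=1e-12)


class TestGatingDrift:
    def test_vanishes_at_equilibrium_across_parameter_grid(self):
        for bias in (-2.0, -0.5, 0.0, 1.0, 3.0):
            for n in (1, 2, 5, 10, 100):
                p = ChannelParams(n=n, eps1=0.0, eps2=0.0, z=1, beta=1.0, V=bias)
                peq = equilibrium_open_probability(p)
                assert abs(open_probability_drift(peq, p, 1.7)) < 1e-12

    def test_vanishes_at_half_open_threshold(self):
        p = ChannelParams(n=3, eps1=1.0, eps2=-1.0, z=2, beta=2.0, V=0.0)
        assert open_probability_drift(0.5, p.at_voltage(p.V0), 1.0) == 0.0

    def test_voltage_term_alone_at_half_open(self):
        # ln[p/(1−p)] = 0 at p = ½ leaves (Γ/n)·bias = 1·1
        p = ChannelParams(n=1, eps1=0.0, eps2=0.0, z=1, beta=1.0, V=1.0)
        assert open_probability_drift(0.5, p, 1.0) == pytest.approx(1.0, rel=1e-14)

    def test_is_free_energy_gradient_flow(self, channel_params):
        # drift(p) = −(Γ/n²) β ∂F/∂x at x = p: the gating equation is the
        # kinetic equation in the open-channel count n₂ = n·x
        land = channel_landscape(channel_params)
        G = 2.0
        for p_open in (0.05, 0.3, 0.5, 0.8, 0.95):
            lhs = open_probability_drift(p_open, channel_params, G)
            rhs = -(G / channel_params.n**2) * channel_params.beta * float(
                land.fprime(p_open)
            )
            assert lhs == pytest.approx(rhs, rel=1e-8)

    def test_domain(self, channel_params):
        with pytest.raises(DomainError):
            open_probability_drift(0.0, channel_params, 1.0)
        with pytest.raises(DomainError):
            open_probability_drift(1.0, channel_params, 1.0)


class TestGatingKinetics:
    grid = UniformGrid(dt=0.01, n_steps=1000)

    def test_equilibrium_start_stays_fixed(self, channel_params):
        peq = equilibrium_open_probability(channel_params)
        traj = simulate_channel(channel_params, 0.6, 1.0, peq, self.grid)
        assert np.max(np.abs(traj.states - peq)) < 1e-12

    def test_markovian_limit_matches_classical_integrator(self):
        p = ChannelParams(n=1, eps1=0.0, eps2=0.0, z=1, beta=1.0, V=0.0)
        grid = UniformGrid(dt=1e-3, n_steps=10_000)
        traj = simulate_channel(p, 1.0, 1.0, 0.1, grid)
        sol = solve_ivp(
            lambda t, y: open_probability_drift(float(y[0]), p, 1.0),
            (0, grid.t_end), [0.1], t_eval=traj.times, rtol=1e-10, atol=1e-12,
        )
        assert np.max(np.abs(traj.states - sol.y[0])) < 1e-5

    def test_fractional_run_reaches_equilibrium_more_slowly(self):
        p = ChannelParams(n=1, eps1=0.0, eps2=0.0, z=1, beta=1.0, V=1.0)
        peq = equilibrium_open_probability(p)
        grid = UniformGrid(dt=0.02, n_steps=10_000)
        frac = simulate_channel(p, 0.7, 1.0, 0.1, grid)
        markov = simulate_channel(p, 1.0, 1.0, 0.1, grid)
        assert abs(frac.states[-1] - peq) < 1e-2
        # the Markovian run closes the gap faster at every late time
        late = grid.times > 10
        assert np.all(
            np.abs(markov.states[late] - peq) < np.abs(frac.states[late] - peq)
        )

    def test_trajectory_stays_inside_unit_interval(self, channel_params):
        for gamma in (0.5, 0.8, 1.0):
            traj = simulate_channel(channel_params, gamma, 2.0, 0.02, self.grid)
            assert np.all((traj.states > 0) & (traj.states < 1))
            assert traj.meta["clamp_count"] == 0

    def test_metadata_records_equilibrium_reference(self, channel_params):
        traj = simulate_channel(channel_params, 0.9, 1.0, 0.1, self.grid)
        assert traj.meta["equilibrium_open_probability"] == pytest.approx(
            equilibrium_open_probability(channel_params)
        )

    def test_step_voltage_protocol_redirects_relaxation(self):
        p = ChannelParams(n=1, eps1=0.0, eps2=0.0, z=1, beta=1.0, V=0.0)
        protocol = step_voltage(-2.0, 2.0, t_switch=5.0)
        grid = UniformGrid(dt=0.01, n_steps=2000)
        traj = simulate_channel(
            p, 1.0, 1.0, 0.5, grid, voltage_protocol=protocol
        )
        mid = np.searchsorted(traj.times, 5.0)
        # hyperpolarized before the step, depolarized after
        assert traj.states[mid - 1] < 0.35
        assert traj.states[-1] > 0.65

    def test_invalid_initial_fraction_rejected(self, channel_params):
        with pytest.raises(DomainError):
            simulate_channel(channel_params, 0.5, 1.0, 0.0, self.grid)
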