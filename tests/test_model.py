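"""Core growth-network model: geometry, dynamics, growth, phases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from socdev import (
    ModelParams,
    apply_gaba_switch,
    apply_inhibition_jump,
    compute_connectivity,
    detect_phase,
    disk_overlap,
    init_network,
    simulate,
    step_dynamics,
    update_growth,
)
from socdev.model import Trajectory

from conftest import small_params


class TestConnectivity:
    @pytest.mark.parametrize(
        "r1, r2, dist, expected",
        [
            (1.0, 1.0, 2.5, 0.0),                      # disjoint
            (1.0, 1.0, 0.0, np.pi),                    # identical disks
            (1.0, 1.0, 1.0, 2 * np.pi / 3 - np.sqrt(3) / 2),  # lens
            (2.0, 0.5, 1.0, np.pi * 0.25),             # contained disk
            (0.0, 1.0, 0.5, 0.0),                      # zero radius
        ],
    )
    def test_disk_overlap_closed_forms(self, r1, r2, dist, expected):
        assert disk_overlap(r1, r2, dist) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_disk_overlap_matches_monte_carlo(self, seed):
        """Lens formula agrees with Monte-Carlo area estimation to ~1%."""
        rng = np.random.default_rng(seed)
        r1, r2 = rng.uniform(0.5, 3.0, 2)
        dist = rng.uniform(0.0, r1 + r2 + 1.0)
        exact = disk_overlap(r1, r2, dist)
        n = 200_000
        # sample inside disk 1, count points inside disk 2
        theta = rng.uniform(0, 2 * np.pi, n)
        rad = r1 * np.sqrt(rng.uniform(0, 1, n))
        x = rad * np.cos(theta)
        y = rad * np.sin(theta)
        inside = (x - dist) ** 2 + y**2 <= r2**2
        mc = np.pi * r1**2 * inside.mean()
        assert mc == pytest.approx(exact, abs=3.0 * np.pi * r1**2 / np.sqrt(n) + 0.01 * exact)

    def test_matrix_properties(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 10, (12, 2))
        a = rng.uniform(0, 4, 12)
        d = rng.uniform(0, 4, 12)
        omega = compute_connectivity(a, d, positions=pos)
        assert omega.shape == (12, 12)
        assert np.all(omega >= 0)
        assert np.all(np.diag(omega) == 0)
        # symmetric only when a == d elementwise
        sym = compute_connectivity(a, a, positions=pos)
        np.testing.assert_allclose(sym, sym.T)

    def test_gaussian_kernel_alternative(self):
        pos = np.array([[0.0, 0.0], [3.0, 0.0]])
        omega = compute_connectivity(
            [1.0, 1.0], [1.0, 1.0], positions=pos, kernel="gaussian"
        )
        assert omega[0, 1] > 0
        assert omega[0, 0] == 0


class TestInit:
    def test_no_initial_connections_and_rest_state(self, params):
        state = init_network(params)
        assert state.omega.max() == 0.0
        assert np.all(state.v == params.v_rest)
        # calcium starts at the spontaneous-firing steady state
        expected_ca = params.tau_ca * params.beta_ca * params.v_rest
        assert np.all(state.ca == pytest.approx(expected_ca))
        assert np.all(state.eps == params.w_exc)

    def test_grid_positions_row_major(self, params):
        state = init_network(params)
        np.testing.assert_allclose(
            state.positions[1] - state.positions[0],
            [params.grid_spacing, 0.0],
        )
        np.testing.assert_allclose(
            state.positions[params.grid_cols] - state.positions[0],
            [0.0, params.grid_spacing],
        )

    def test_single_neuron_degenerate(self):
        p = small_params(n_neurons=1, grid_rows=1, grid_cols=1)
        raster, traj, _ = simulate(p, 50)
        assert len(traj) == 50

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="grid capacity"):
            small_params(n_neurons=26)

    def test_same_seed_identical_state(self, params):
        s1 = init_network(params)
        s2 = init_network(params)
        np.testing.assert_array_equal(s1.v, s2.v)
        assert s1.rng.random() == s2.rng.random()


class TestDynamics:
    def test_spike_probability_equals_potential(self, params):
        """With zero connectivity, P(spike) = v for eligible neurons."""
        p = small_params(v_rest=0.3, tau_v=1e12)  # hold v at 0.3
        state = init_network(p)
        spikes = np.zeros(p.n_neurons)
        eligible = np.zeros(p.n_neurons)
        for _ in range(4000):
            free = state.refrac_count == 0
            s = step_dynamics(state, p)
            spikes += s
            eligible += free
        rate = spikes.sum() / eligible.sum()
        assert rate == pytest.approx(0.3, abs=0.02)

    def test_refractory_period_blocks_spikes(self, params):
        state = init_network(params)
        hist = []
        for _ in range(200):
            state.v[:] = 1.0
            hist.append(step_dynamics(state, params).copy())
        H = np.array(hist)
        # a spiking neuron is silent for the next refractory_steps steps
        for j in range(params.n_neurons):
            gaps = np.diff(np.flatnonzero(H[:, j]))
            assert np.all(gaps >= params.refractory_steps + 1)

    def test_rate_ceiling_at_pinned_potential(self, params):
        state = init_network(params)
        total = 0
        n_steps = 1000
        for _ in range(n_steps):
            state.v[:] = 1.0
            total += step_dynamics(state, params).sum()
        rate = total / (n_steps * params.n_neurons)
        assert rate <= 1.0 / (params.refractory_steps + 1) + 1e-12

    def test_hard_bound_on_v(self):
        p = small_params()
        _, traj, state = simulate(p, 3000)
        assert state.v.max() <= 1.0
        assert traj.v_mean.max() <= 1.0
        assert state.v.min() >= 0.0


class TestGrowth:
    def test_at_target_nothing_changes(self, params):
        state = init_network(params)
        state.ca[:] = params.ca_target
        a0, d0, om0 = state.a.copy(), state.d.copy(), state.omega.copy()
        update_growth(state, params)
        np.testing.assert_array_equal(state.a, a0)
        np.testing.assert_array_equal(state.d, d0)
        np.testing.assert_array_equal(state.omega, om0)

    def test_low_calcium_grows_dendrite_shrinks_axon(self, params):
        state = init_network(params)
        state.ca[:] = 0.1 * params.ca_target
        a0, d0 = state.a.copy(), state.d.copy()
        update_growth(state, params)
        assert np.all(state.d > d0)
        assert np.all(state.a < a0)

    def test_high_calcium_shrinks_dendrite_grows_axon(self, params):
        state = init_network(params)
        state.ca[:] = 3.0 * params.ca_target
        state.d[:] = 2.0
        a0, d0 = state.a.copy(), state.d.copy()
        update_growth(state, params)
        assert np.all(state.d < d0)
        assert np.all(state.a > a0)

    def test_fields_clipped_at_zero(self, params):
        state = init_network(params)
        state.ca[:] = 100 * params.ca_target
        state.d[:] = 1e-6
        for _ in range(5):
            update_growth(state, params)
        assert np.all(state.d >= 0)


class TestGabaSwitch:
    def test_exact_inhibitory_count(self):
        p = small_params(n_neurons=25, inhib_fraction=0.2)
        state = init_network(p)
        chosen = apply_gaba_switch(state, p)
        assert chosen.size == 5
        assert np.count_nonzero(state.eps < 0) == 5
        assert np.all(state.eps[chosen] == -p.w_inh)

    def test_double_switch_raises(self, params):
        state = init_network(params)
        apply_gaba_switch(state, params)
        with pytest.raises(RuntimeError):
            apply_gaba_switch(state, params)

    def test_zero_fraction_noop(self):
        p = small_params(inhib_fraction=0.0)
        state = init_network(p)
        apply_gaba_switch(state, p)
        assert state.gaba_switched
        assert np.all(state.eps == p.w_exc)

    def test_equal_weights_equal_magnitude(self):
        p = small_params(w_inh=0.02)
        state = init_network(p)
        apply_gaba_switch(state, p)
        assert np.all(np.abs(state.eps) == p.w_exc)


class TestInhibitionJump:
    def test_requires_switched_network(self, params):
        state = init_network(params)
        with pytest.raises(RuntimeError):
            apply_inhibition_jump(state, 0.01)

    def test_same_value_is_noop(self, params):
        state = init_network(params)
        apply_gaba_switch(state, params)
        eps0 = state.eps.copy()
        apply_inhibition_jump(state, params.w_inh)
        np.testing.assert_array_equal(state.eps, eps0)

    def test_negative_raises(self, params):
        state = init_network(params)
        apply_gaba_switch(state, params)
        with pytest.raises(ValueError):
            apply_inhibition_jump(state, -0.1)


class TestSimulate:
    def test_seed_reproducibility(self, params):
        r1, t1, _ = simulate(params, 400)
        r2, t2, _ = simulate(params, 400)
        np.testing.assert_array_equal(r1.times, r2.times)
        np.testing.assert_array_equal(r1.units, r2.units)
        np.testing.assert_array_equal(t1.ca_mean, t2.ca_mean)

    def test_switch_fires_at_ca_crossing(self):
        p = small_params()
        _, traj, state = simulate(p, 4000)
        assert state.gaba_switched
        assert traj.switch_time is not None
        # mean calcium was below target before the switch
        pre = traj.ca_mean[traj.t < traj.switch_time]
        assert np.all(pre < p.ca_target)

    def test_fixed_step_switch_policy(self):
        p = small_params()
        _, traj, _ = simulate(p, 300, switch_policy=("step", 100))
        assert traj.switch_time == 100

    def test_never_policy(self):
        p = small_params()
        _, _, state = simulate(p, 500, switch_policy="never")
        assert not state.gaba_switched


class TestDetectPhase:
    def _traj(self, ca, target):
        n = len(ca)
        z = np.zeros(n)
        return Trajectory(
            t=np.arange(n, dtype=float), v_mean=z, ca_mean=np.asarray(ca, dtype=float),
            a_mean=z, d_mean=z, omega_mean=z, rate=z, ca_target=target,
        )

    def test_development_passes_phases_in_order(self):
        # full-size network: small populations are too noisy for the
        # homeostasis window to latch
        p = ModelParams(ca_target=30.0, grid_spacing=4.0, init_a=3.9, seed=0)
        _, traj, _ = simulate(p, 12000)
        labels = detect_phase(traj, p, ca_tol=0.1, window=500)
        order = {"I": 0, "II": 1, "III": 2}
        codes = np.array([order[x] for x in labels])
        assert np.all(np.diff(codes) >= 0), "phases must not reverse"
        assert codes[0] == 0 and codes[-1] == 2

    def test_all_homeostatic_is_single_phase_three(self, params):
        traj = self._traj(np.full(300, params.ca_target), params.ca_target)
        labels = detect_phase(traj, params)
        assert set(labels) == {"III"}

    def test_subtarget_calcium_is_all_phase_one(self, params):
        traj = self._traj(np.linspace(0, 0.9 * params.ca_target, 300),
                          params.ca_target)
        labels = detect_phase(traj, params)
        assert set(labels) == {"I"}

    def test_empty_trajectory_raises(self, params):
        with pytest.raises(ValueError):
            detect_phase(self._traj([], params.ca_target), params)
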