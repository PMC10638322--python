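"""Unit and property tests for the network dynamics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numercode.dynamics import (
    NetworkParams,
    NetworkState,
    SimulationConfig,
    StimulusSpec,
    activation,
    analytic_fixed_point,
    ensemble_mean_activation,
    euler_step,
    mean_activation,
    simulate_run,
)


class TestActivation:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.0, 0.0), (1.0, 0.5), (-3.0, 0.0), (0.25, 0.2), (9.0, 0.9)],
    )
    def test_values(self, x, expected):
        assert activation(x) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            activation(float("nan"))
        with pytest.raises(ValueError):
            activation(np.array([1.0, np.inf]))

    @given(st.floats(-100, 100), st.floats(-100, 100))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone(self, a, b):
        fa, fb = activation(a), activation(b)
        assert 0.0 <= fa < 1.0
        if a <= b:
            assert fa <= fb


def _scalar_loop_step(x, params, drive, noise, dt):
    """Independent brute-force update: plain python loop over units."""
    n = len(x)
    fx = [xi / (1 + xi) if xi > 0 else 0.0 for xi in x]
    out = []
    for i in range(n):
        inhib = sum(fx[j] for j in range(n) if j != i)
        dx = (
            -params.lam * x[i]
            + params.alpha * fx[i]
            - params.beta * inhib
            + drive[i]
            + noise[i]
        )
        out.append(max(x[i] + dt * dx, 0.0))
    return np.array(out)


class TestEulerStep:
    def test_fixed_point_is_stationary(self):
        # two uncoupled units resting at the self-excitation fixed point
        # x* = alpha/lam - 1 = 1.2
        params = NetworkParams(n_nodes=2, alpha=2.2, beta=0.0, lam=1.0, noise_sd=0.0)
        state = NetworkState(np.array([1.2, 1.2]))
        new = euler_step(state, params, np.zeros(2), np.zeros(2), dt=1.0)
        assert new.activations == pytest.approx([1.2, 1.2])
        assert new.t == 1

    def test_drive_only_from_rest(self):
        params = NetworkParams(n_nodes=4, noise_sd=0.0)
        state = NetworkState(np.zeros(4))
        drive = np.array([1.0, 0, 0, 0])
        new = euler_step(state, params, drive, np.zeros(4), dt=1.0)
        assert new.activations == pytest.approx([1.0, 0, 0, 0])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_scalar_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        params = NetworkParams(
            n_nodes=5, alpha=2.2, beta=float(rng.uniform(0, 0.2)), lam=1.0
        )
        x = rng.uniform(-1, 3, 5)
        drive = rng.uniform(0, 1, 5)
        noise = rng.normal(0, 0.03, 5)
        state = NetworkState(x.copy())
        got = euler_step(state, params, drive, noise, dt=1.0).activations
        want = _scalar_loop_step(x, params, drive, noise, 1.0)
        np.testing.assert_allclose(got, want, rtol=0, atol=1e-14)

    def test_length_mismatch_raises(self):
        params = NetworkParams(n_nodes=4)
        state = NetworkState(np.zeros(4))
        with pytest.raises(ValueError):
            euler_step(state, params, np.zeros(3), np.zeros(4))


class TestMeanActivation:
    def test_zero_state(self):
        assert mean_activation(NetworkState(np.zeros(64))) == 0.0

    def test_single_active_unit(self):
        x = np.zeros(64)
        x[0] = 1.2
        assert mean_activation(NetworkState(x)) == pytest.approx(1.2 / 64)

    def test_matches_loop(self, rng):
        x = rng.uniform(0, 5, 64)
        want = sum(float(v) for v in x) / 64
        assert mean_activation(NetworkState(x)) == pytest.approx(want, rel=1e-12)


class TestSimulateRun:
    def test_noise_free_single_input_converges(self):
        # with no inhibition and no noise the driven unit settles at
        # alpha/lam - 1 = 1.2; everyone else stays silent
        params = NetworkParams(beta=0.0, noise_sd=0.0)
        state, ma = simulate_run(
            params, StimulusSpec(set_size=1), SimulationConfig(total_steps=5000)
        )
        assert state.activations[0] == pytest.approx(1.2, abs=1e-6)
        assert np.all(state.activations[1:] == 0)
        assert ma == pytest.approx(1.2 / 64, abs=1e-6)

    def test_empty_input_stays_at_rest(self):
        params = NetworkParams(noise_sd=0.0)
        _, ma = simulate_run(
            params, StimulusSpec(set_size=0), SimulationConfig(total_steps=500)
        )
        assert ma == 0.0

    def test_set_size_exceeding_network_raises(self):
        with pytest.raises(ValueError):
            simulate_run(
                NetworkParams(n_nodes=4),
                StimulusSpec(set_size=5),
                SimulationConfig(total_steps=10),
            )

    @pytest.mark.parametrize("k,beta", [(1, 0.01), (5, 0.02), (10, 0.02)])
    def test_converges_to_analytic_fixed_point(self, k, beta):
        # weak-inhibition stable regime: simulated steady state matches the
        # closed-form symmetric solution to 1e-6
        params = NetworkParams(beta=beta, noise_sd=0.0)
        state, _ = simulate_run(
            params, StimulusSpec(set_size=k), SimulationConfig(total_steps=5000)
        )
        x_active, x_inactive = analytic_fixed_point(k, params)
        np.testing.assert_allclose(state.activations[:k], x_active, atol=1e-6)
        np.testing.assert_allclose(state.activations[k:], x_inactive, atol=1e-6)

    def test_permutation_symmetry_of_driven_nodes(self):
        # which units are driven is immaterial for the readout
        params = NetworkParams(beta=0.05, noise_sd=0.0)
        config = SimulationConfig(total_steps=2000)
        _, ma_default = simulate_run(params, StimulusSpec(set_size=3), config)
        _, ma_shuffled = simulate_run(
            params,
            StimulusSpec(set_size=3, node_indices=(63, 17, 4)),
            config,
        )
        assert ma_shuffled == pytest.approx(ma_default, rel=1e-12)


class TestEnsemble:
    def test_noise_free_ensemble_equals_single_run(self):
        params = NetworkParams(beta=0.05, noise_sd=0.0)
        config = SimulationConfig(total_steps=1000, n_runs=5, seed=7)
        mean, sd = ensemble_mean_activation(params, StimulusSpec(set_size=3), config)
        _, single = simulate_run(params, StimulusSpec(set_size=3), config)
        assert mean == pytest.approx(single, rel=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-15)

    def test_bit_reproducible_given_seed(self):
        params = NetworkParams(beta=0.1)
        config = SimulationConfig(total_steps=300, n_runs=4, seed=99)
        a = ensemble_mean_activation(params, StimulusSpec(set_size=4), config)
        b = ensemble_mean_activation(params, StimulusSpec(set_size=4), config)
        assert a == b

    def test_different_seeds_differ(self):
        params = NetworkParams(beta=0.1)
        stim = StimulusSpec(set_size=4)
        a, _ = ensemble_mean_activation(
            params, stim, SimulationConfig(total_steps=300, n_runs=2, seed=1)
        )
        b, _ = ensemble_mean_activation(
            params, stim, SimulationConfig(total_steps=300, n_runs=2, seed=2)
        )
        assert a != b

    def test_ensemble_mean_stabilises_with_size(self):
        # law of large numbers: a small ensemble's mean lies within
        # 3 sd / sqrt(n) of a 10x larger ensemble's mean
        params = NetworkParams(beta=0.1)
        stim = StimulusSpec(set_size=4)
        small = SimulationConfig(total_steps=1500, n_runs=6, seed=5)
        large = SimulationConfig(total_steps=1500, n_runs=60, seed=5)
        m_small, sd_small = ensemble_mean_activation(params, stim, small)
        m_large, _ = ensemble_mean_activation(params, stim, large)
        assert abs(m_small - m_large) <= 3 * sd_small / np.sqrt(small.n_runs) + 1e-9

    def test_batched_ensemble_matches_sequential_runs(self):
        # the vectorised kernel must reproduce run-by-run simulation
        from numercode.dynamics import run_seed_sequence

        params = NetworkParams(beta=0.08)
        stim = StimulusSpec(set_size=3)
        config = SimulationConfig(total_steps=400, n_runs=3, seed=11)
        mean_batch, _ = ensemble_mean_activation(params, stim, config)
        singles = []
        for r in range(config.n_runs):
            rng = np.random.default_rng(
                run_seed_sequence(config.seed, stim.set_size, params.beta, r)
            )
            _, ma = simulate_run(params, stim, config, rng=rng)
            singles.append(ma)
        assert mean_batch == pytest.approx(np.mean(singles), rel=1e-12)


class TestAnalyticFixedPoint:
    def test_single_winner_independent_of_beta(self):
        for beta in (0.0, 0.05, 0.15):
            x_active, _ = analytic_fixed_point(1, NetworkParams(beta=beta))
            assert x_active == pytest.approx(1.2)

    def test_extinction_boundary(self):
        # gain below decay: no sustained activity
        params = NetworkParams(beta=0.15)
        k = 10  # alpha - beta*(k-1) = 0.85 < lam
        x_active, x_inactive = analytic_fixed_point(k, params)
        assert x_active == 0.0
        assert x_inactive == 0.0

    def test_unrectified_branch_matches_algebra(self):
        params = NetworkParams(beta=0.01, lam=1.0)
        x_active, x_inactive = analytic_fixed_point(5, params, rectified=False)
        assert x_active == pytest.approx((2.2 - 0.04) / 1.0 - 1.0)
        assert x_inactive == pytest.approx(-0.05 * (1.16 / 2.16))

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            analytic_fixed_point(65, NetworkParams())


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_nodes": 0},
            {"alpha": 0.0},
            {"beta": -0.1},
            {"lam": 0.0},
            {"noise_sd": -1.0},
        ],
    )
    def test_bad_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NetworkParams(**kwargs)

    def test_bad_stimulus_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(set_size=2, node_indices=(1,))
        with pytest.raises(ValueError):
            StimulusSpec(set_size=2, node_indices=(1, 1))
        with pytest.raises(ValueError):
            StimulusSpec(set_size=-1)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(total_steps=0)
        with pytest.raises(ValueError):
            SimulationConfig(steady_window=0)
        with pytest.raises(ValueError):
            SimulationConfig(n_runs=0)
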