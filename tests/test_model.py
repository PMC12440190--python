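"""Neuron model: presets, vector field, reset, noise, forward simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikesde import (
    ControlSignal,
    IzhikevichParams,
    SimulationGrid,
    apply_reset,
    drift_u,
    drift_v,
    preset_params,
    sample_noise,
    simulate_reset,
)


@pytest.mark.parametrize(
    "name, expected",
    [
        ("RS", (0.02, 0.2, -65.0, 8.0)),
        ("IB", (0.02, 0.2, -55.0, 4.0)),
        ("CH", (0.02, 0.2, -50.0, 2.0)),
        ("FS", (0.1, 0.2, -65.0, 2.0)),
    ],
)
def test_preset_parameters(name, expected):
    p = preset_params(name)
    assert (p.a, p.b, p.c, p.d) == expected
    assert p.v_peak == 30.0
    assert p.pattern_name == name


def test_unknown_preset_names_valid_labels():
    with pytest.raises(ValueError, match="CH.*FS.*IB.*RS"):
        preset_params("LIF")


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        IzhikevichParams(a=-0.1, b=0.2, c=-65.0, d=8.0)
    with pytest.raises(ValueError):
        IzhikevichParams(a=0.02, b=0.2, c=40.0, d=8.0, v_peak=30.0)


@pytest.mark.parametrize(
    "v, u, I, expected",
    [(-65.0, -13.0, 0.0, 0.0), (-65.0, -13.0, 10.0, 7.0), (0.0, 0.0, 0.0, 140.0)],
)
def test_drift_v_examples(v, u, I, expected):
    assert drift_v(v, u, I) == pytest.approx(expected)


@settings(max_examples=200, deadline=None)
@given(
    v=st.floats(-200, 200),
    u=st.floats(-100, 100),
    I=st.floats(-100, 100),
)
def test_drift_v_rectified_nonnegative(v, u, I):
    assert drift_v(v, u, I) >= 0.0


@pytest.mark.parametrize(
    "v, u, expected",
    [(-65.0, -13.0, 0.0), (-65.0, 0.0, -0.26), (0.0, 0.0, 0.0)],
)
def test_drift_u_examples(rs, v, u, expected):
    assert drift_u(v, u, rs) == pytest.approx(expected)


def test_apply_reset(rs):
    assert apply_reset(30.0, -13.0, rs) == (-65.0, -5.0, True)
    assert apply_reset(20.0, -13.0, rs) == (20.0, -13.0, False)
    # overshoot of 5 mV carried past the reset
    v, u, fired = apply_reset(35.0, 0.0, rs, carry_overshoot=True)
    assert (v, u, fired) == (pytest.approx(-60.0), 8.0, True)


class TestNoise:
    def test_negative_beta_rejected(self, grid_5ms):
        with pytest.raises(ValueError):
            sample_noise(grid_5ms, -0.5, 0)

    def test_reproducible_from_seed(self, grid_5ms):
        a = sample_noise(grid_5ms, 1.0, 7)
        b = sample_noise(grid_5ms, 1.0, 7)
        assert np.array_equal(a.increments, b.increments)

    def test_increment_variance_matches_step(self):
        grid = SimulationGrid(h=0.1, t_size=100_000)
        noise = sample_noise(grid, 1.0, 3)
        assert np.var(noise.increments) == pytest.approx(0.1, rel=0.05)
        assert len(noise.increments) == grid.t_size


class TestSimulateReset:
    def test_rest_state_is_constant(self, rs, grid_5ms):
        control = ControlSignal.zeros(grid_5ms)
        noise = sample_noise(grid_5ms, 0.0, 0)
        traj, train = simulate_reset(rs, control, noise)
        assert train.count == 0
        assert np.allclose(traj.v, -65.0)
        assert np.allclose(traj.u, -13.0)

    def test_grid_mismatch_rejected(self, rs, grid_5ms):
        control = ControlSignal.zeros(grid_5ms)
        noise = sample_noise(SimulationGrid(h=0.1, t_size=30), 0.0, 0)
        with pytest.raises(ValueError, match="grid"):
            simulate_reset(rs, control, noise)

    def test_samples_capped_at_peak_without_carry(self, rs, grid_10ms):
        control = ControlSignal.constant(grid_10ms, 30.0)
        noise = sample_noise(grid_10ms, 1.0, 11)
        traj, train = simulate_reset(rs, control, noise)
        assert train.count > 0
        assert np.max(traj.v) <= rs.v_peak

    def test_spike_times_ordered_inside_horizon(self, rs, grid_10ms):
        control = ControlSignal.constant(grid_10ms, 20.0)
        noise = sample_noise(grid_10ms, 1.0, 5)
        _, train = simulate_reset(rs, control, noise)
        assert train.count >= 1
        assert np.all(np.diff(train.times) > 0)
        assert train.times[0] > 0 and train.times[-1] <= grid_10ms.T

    def test_first_spike_converges_to_fine_step_reference(self, rs):
        """Euler first-spike error vs an h=0.001 reference shrinks ~linearly in h."""

        def first_spike(h, t_size):
            grid = SimulationGrid(h=h, t_size=t_size)
            _, train = simulate_reset(
                rs, ControlSignal.constant(grid, 10.0), sample_noise(grid, 0.0, 0)
            )
            assert train.count >= 1
            return train.times[0]

        ref = first_spike(0.001, 10_000)
        err_coarse = abs(first_spike(0.1, 100) - ref)
        err_half = abs(first_spike(0.05, 200) - ref)
        assert err_coarse <= 2 * 0.1  # within two coarse steps
        assert err_half < err_coarse  # first-order trend

    def test_halving_step_moves_spikes_by_at_most_coarse_step(self, rs):
        """First-order convergence: spike times shift by <= h when h halves."""

        def spikes_at(h):
            grid = SimulationGrid.from_horizon(10.0, h)
            values = np.zeros(grid.t_size)
            j0, j1 = int(round(1.0 / h)), int(round(3.0 / h))
            values[j0:j1] = 20.0  # fixed pulse input
            _, train = simulate_reset(
                rs, ControlSignal(values, grid), sample_noise(grid, 0.0, 0)
            )
            return train.times

        coarse, fine = spikes_at(0.1), spikes_at(0.05)
        n = min(len(coarse), len(fine))
        assert n >= 1
        assert np.all(np.abs(coarse[:n] - fine[:n]) <= 0.1)

    def test_bit_reproducible(self, rs, grid_10ms):
        control = ControlSignal.constant(grid_10ms, 12.0)
        runs = [
            simulate_reset(rs, control, sample_noise(grid_10ms, 1.0, 9))
            for _ in range(2)
        ]
        assert np.array_equal(runs[0][0].v, runs[1][0].v)
        assert np.array_equal(runs[0][1].times, runs[1][1].times)
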