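"""Gradient engines, the finite-difference oracle, and the training loop."""

import numpy as np
import pytest

from spikesde import (
    ControlSignal,
    LossWeights,
    SimulationGrid,
    SpikeTarget,
    TrainConfig,
    clip_control,
    control_gradient,
    finite_difference_gradient,
    init_control,
    preset_params,
    sample_noise,
    simulate_reset,
    train_control,
)


def test_init_control_is_zero_baseline(grid_10ms):
    control = init_control(grid_10ms)
    assert np.all(control.values == 0.0)
    assert len(control.values) == grid_10ms.t_size
    single = init_control(SimulationGrid(h=0.1, t_size=1))
    assert single.values.tolist() == [0.0]


def test_clip_control_projects_to_box(grid_5ms):
    values = np.array([150.0, -150.0, 50.0] + [0.0] * 47)
    clipped = clip_control(values, -100.0, 100.0)
    assert clipped[0] == 100.0
    assert clipped[1] == -100.0
    assert clipped[2] == 50.0
    control = ControlSignal.constant(grid_5ms, 50.0)
    assert np.array_equal(clip_control(control).values, control.values)


def _relative_errors(rev, fd):
    denom = np.maximum(np.maximum(np.abs(fd), np.abs(rev)), 1e-6)
    return np.abs(rev - fd) / denom


@pytest.mark.parametrize("simulator", ["transformed", "reset"])
@pytest.mark.parametrize("beta", [0.0, 1.0])
def test_reverse_mode_matches_finite_differences(rs, grid_5ms, toy_target,
                                                 toy_control, simulator, beta):
    """Exact-mode backprop vs central differences on a 50-step toy task."""
    noise = sample_noise(grid_5ms, beta, 42)
    rev = control_gradient(rs, toy_target, toy_control, noise, LossWeights(),
                           leak=0.0, simulator=simulator)
    fd = finite_difference_gradient(rs, toy_target, toy_control, noise,
                                    LossWeights(), eps=1e-5, simulator=simulator)
    assert np.max(_relative_errors(rev, fd)) < 1e-3


def test_fd_error_shrinks_as_eps_halves(rs, grid_5ms, toy_target, toy_control):
    """Richardson behavior: the central-difference error falls with eps."""
    noise = sample_noise(grid_5ms, 0.0, 0)
    rev = control_gradient(rs, toy_target, toy_control, noise, LossWeights(),
                           leak=0.0)
    errs = []
    for eps in (1e-2, 5e-3):
        fd = finite_difference_gradient(rs, toy_target, toy_control, noise,
                                        LossWeights(), eps=eps)
        errs.append(np.max(np.abs(fd - rev)))
    assert errs[1] < errs[0]


def test_gradient_zero_in_inactive_region(rs, grid_5ms):
    """No spikes desired, rectifier inactive everywhere: exact gradient is 0."""
    target = SpikeTarget(times=np.array([]), horizon=5.0)
    control = init_control(grid_5ms)
    noise = sample_noise(grid_5ms, 0.0, 0)
    grad = control_gradient(rs, target, control, noise, LossWeights(), leak=0.0)
    assert np.all(grad == 0.0)


def test_fd_requires_positive_eps(rs, grid_5ms, toy_target, toy_control):
    with pytest.raises(ValueError):
        finite_difference_gradient(rs, toy_target, toy_control,
                                   sample_noise(grid_5ms, 0.0, 0),
                                   LossWeights(), eps=0.0)


class TestTrainControl:
    def test_invalid_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    def test_horizon_mismatch_rejected(self, rs):
        target = SpikeTarget(times=np.array([3.0]), horizon=20.0)
        config = TrainConfig(grid=SimulationGrid(h=0.1, t_size=50))
        with pytest.raises(ValueError, match="horizon"):
            train_control(rs, target, config)

    def test_deterministic_single_target_converges(self, rs):
        """beta=0, one desired spike at 3.0 ms: within one grid step."""
        target = SpikeTarget(times=np.array([3.0]), horizon=5.0)
        control, trace = train_control(rs, target, TrainConfig(beta=0.0, seed=1))
        _, train = simulate_reset(
            rs, control, sample_noise(control.grid, 0.0, 0)
        )
        assert train.count >= 1
        assert abs(train.times[0] - 3.0) <= 0.1
        assert len(trace) == 100

    def test_deterministic_loss_non_increasing_after_transient(self, rs):
        target = SpikeTarget(times=np.array([3.0]), horizon=5.0)
        _, trace = train_control(rs, target, TrainConfig(beta=0.0, seed=1))
        tail = trace.batch_losses[10:]
        assert np.all(np.diff(tail) <= 1e-9)

    def test_returned_control_respects_bounds(self, rs):
        target = SpikeTarget(times=np.array([1.0, 3.0]), horizon=5.0)
        control, _ = train_control(rs, target, TrainConfig(beta=1.0, seed=2))
        assert control.values.min() >= control.lower_bound
        assert control.values.max() <= control.upper_bound

    def test_bit_reproducible_from_seed(self, rs):
        target = SpikeTarget(times=np.array([2.0, 4.0]), horizon=5.0)
        config = TrainConfig(beta=1.0, seed=3, epochs=20)
        a, _ = train_control(rs, target, config)
        b, _ = train_control(rs, target, config)
        assert np.array_equal(a.values, b.values)

    @pytest.mark.parametrize("optimizer", ["adam", "sgd"])
    def test_reference_optimizers_run(self, rs, optimizer):
        target = SpikeTarget(times=np.array([2.0]), horizon=5.0)
        config = TrainConfig(optimizer=optimizer, epochs=5, beta=0.0, seed=0,
                             learning_rate=0.5 if optimizer == "adam" else 1e-3)
        control, trace = train_control(rs, target, config)
        assert len(trace) == 5
        assert np.all(np.isfinite(trace.batch_losses))
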