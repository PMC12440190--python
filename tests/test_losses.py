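"""Spike-timing loss components and the three-case composite."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikesde import (
    LossWeights,
    SimulationGrid,
    SpikeTarget,
    SpikeTrain,
    batch_loss,
    composite_loss,
    loss_overfire,
    loss_timing,
    loss_underfire,
    preset_params,
)

GRID = SimulationGrid(h=1.0, t_size=4)
V_SAMPLES = np.array([-65.0, -65.0, -65.0, -60.0, -55.0])


@pytest.mark.parametrize(
    "t, td, expected", [(1.5, 1.0, 0.25), (3.0, 3.0, 0.0), (2.9, 3.0, 0.01)]
)
def test_timing_loss(t, td, expected):
    assert loss_timing(t, td) == pytest.approx(expected)


class TestUnderfire:
    def test_zero_weight(self, rs):
        train = SpikeTrain(times=np.array([2.0]))
        assert loss_underfire(V_SAMPLES, train, rs, LossWeights(w1=0.0), GRID) == 0.0

    def test_zero_residual_at_threshold(self, rs):
        v = np.full(5, rs.v_peak)
        train = SpikeTrain(times=np.array([2.0]))
        assert loss_underfire(v, train, rs, LossWeights(w1=1.0), GRID) == 0.0

    def test_hand_computed_window(self, rs):
        # window from the last spike at 2.0 ms: residuals 95, 90, 85
        train = SpikeTrain(times=np.array([2.0]))
        value = loss_underfire(V_SAMPLES, train, rs, LossWeights(w1=1.0), GRID)
        assert value == pytest.approx(24350.0)


class TestOverfire:
    def test_zero_weight(self, rs):
        train = SpikeTrain(times=np.array([1.0, 3.0, 3.5]))
        target = SpikeTarget(times=np.array([1.0, 3.0]), horizon=4.0)
        assert loss_overfire(V_SAMPLES, train, target, rs,
                             LossWeights(w2=0.0), GRID) == 0.0

    def test_zero_residual_at_reset(self, rs):
        v = np.full(5, rs.c)
        train = SpikeTrain(times=np.array([1.0, 3.0, 3.5]))
        target = SpikeTarget(times=np.array([1.0, 3.0]), horizon=4.0)
        assert loss_overfire(v, train, target, rs, LossWeights(w2=1.0), GRID) == 0.0

    def test_hand_computed_window(self, rs):
        # window from the 2nd actual spike at 3.0 ms: residuals 5, 10
        train = SpikeTrain(times=np.array([1.0, 3.0, 3.5]))
        target = SpikeTarget(times=np.array([1.0, 3.0]), horizon=4.0)
        value = loss_overfire(V_SAMPLES, train, target, rs, LossWeights(w2=1.0), GRID)
        assert value == pytest.approx(125.0)


class TestComposite:
    def test_match_case(self, rs):
        train = SpikeTrain(times=np.array([1.5, 3.0]))
        target = SpikeTarget(times=np.array([1.0, 3.0]), horizon=4.0)
        bd = composite_loss(V_SAMPLES, train, target, rs, LossWeights(), GRID)
        assert bd.active_case == "match"
        assert bd.total == pytest.approx(0.25)
        assert bd.l2 == bd.l3 == 0.0

    def test_underfire_case(self, rs):
        train = SpikeTrain(times=np.array([2.0]))
        target = SpikeTarget(times=np.array([2.0, 3.5]), horizon=4.0)
        bd = composite_loss(V_SAMPLES, train, target, rs, LossWeights(w1=1.0), GRID)
        assert bd.active_case == "underfire"
        assert bd.total == pytest.approx(24350.0)  # l1(1) = 0 at the exact match

    def test_overfire_case(self, rs):
        train = SpikeTrain(times=np.array([1.0, 3.0, 3.5]))
        target = SpikeTarget(times=np.array([1.0, 3.0]), horizon=4.0)
        bd = composite_loss(V_SAMPLES, train, target, rs,
                            LossWeights(w2=1.0), GRID)
        assert bd.active_case == "overfire"
        assert bd.total == pytest.approx(125.0)  # first two spikes exact

    def test_components_reconstruct_total(self, rs):
        train = SpikeTrain(times=np.array([1.4]))
        target = SpikeTarget(times=np.array([1.0, 3.0]), horizon=4.0)
        bd = composite_loss(V_SAMPLES, train, target, rs, LossWeights(w1=0.5), GRID)
        assert bd.total == pytest.approx(float(np.sum(bd.l1_terms)) + bd.l2 + bd.l3)

    def test_zero_iff_exact_match(self, rs):
        target = SpikeTarget(times=np.array([1.0, 3.0]), horizon=4.0)
        exact = SpikeTrain(times=np.array([1.0, 3.0]))
        bd = composite_loss(V_SAMPLES, exact, target, rs, LossWeights(w1=1.0), GRID)
        assert bd.total == 0.0
        off = SpikeTrain(times=np.array([1.0, 3.1]))
        assert composite_loss(V_SAMPLES, off, target, rs,
                              LossWeights(w1=1.0), GRID).total > 0


@settings(max_examples=100, deadline=None)
@given(
    shifts=st.lists(st.floats(-0.5, 0.5), min_size=2, max_size=2),
    scale=st.floats(0.1, 3.0),
)
def test_timing_sum_scales_quadratically(shifts, scale):
    rs = preset_params("RS")
    target = SpikeTarget(times=np.array([1.0, 3.0]), horizon=5.0)
    grid = SimulationGrid(h=1.0, t_size=5)
    v = np.full(6, rs.c)

    def total(factor):
        times = target.times + factor * np.asarray(shifts)
        if np.any(np.diff(times) <= 0):
            return None
        train = SpikeTrain(times=times)
        return composite_loss(v, train, target, rs, LossWeights(), grid).total

    base, scaled = total(1.0), total(scale)
    if base is None or scaled is None:
        return
    assert scaled == pytest.approx(scale ** 2 * base, rel=1e-9, abs=1e-12)


def test_batch_loss():
    assert batch_loss([4.0]) == 4.0
    assert batch_loss([2.0, 2.0]) == 2.0
    assert batch_loss([1.0, 2.0, 3.0, 4.0, 5.0]) == 3.0
    with pytest.raises(ValueError):
        batch_loss([])
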