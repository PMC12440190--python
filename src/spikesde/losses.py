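"""Spike-timing loss functions.

Three components steer the learned current:

* timing loss  ``l1(k) = (t_k - t_hat_k)^2`` per paired spike,
* underfiring penalty ``l2 = sum w1 (v_f - v(h k))^2`` over the samples from
  the last actual spike to the end of the horizon (drives ``v`` up so the
  missing spikes appear),
* overfiring penalty ``l3 = sum w2 (v(h k) - c)^2`` over the samples from
  the time of the N_hat-th actual spike onwards (drives ``v`` down so the
  excess spikes disappear).

The composite loss uses exactly one case depending on the actual spike count
``N`` versus the desired count ``N_hat``::

    l = sum_{k<=N_hat} l1(k)            if N == N_hat
    l = l2 + sum_{k<=N}     l1(k)       if N <  N_hat
    l = l3 + sum_{k<=N_hat} l1(k)       otherwise

The k-th actual spike is always paired with the k-th desired time.  The case
and the pairing are constants of a forward pass: gradients flow through the
trajectory samples and the interpolated spike times only, never through the
(integer-valued) spike count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import IzhikevichParams, SimulationGrid, SpikeTrain, Trajectory
from .transform import TransformedTrajectory, phi

__all__ = [
    "SpikeTarget",
    "LossWeights",
    "LossBreakdown",
    "loss_timing",
    "loss_underfire",
    "loss_overfire",
    "composite_loss",
    "batch_loss",
    "window_start_index",
]


@dataclass(frozen=True)
class SpikeTarget:
    """Desired firing times ``t_hat_k`` inside a horizon ``[0, T]``."""

    times: np.ndarray
    horizon: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("desired times must be one-dimensional")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("desired times must be strictly increasing")
        if len(times) and (times[0] <= 0 or times[-1] >= self.horizon):
            raise ValueError(
                f"desired times must lie strictly inside (0, {self.horizon})"
            )

    @property
    def count(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class LossWeights:
    """Non-negative weights of the underfire (w1) and overfire (w2) penalties.

    Defaults are small (0.01) so that the mV^2-scale penalty sums do not
    dwarf the ms^2-scale timing loss.
    """

    w1: float = 0.01
    w2: float = 0.01

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass(frozen=True)
class LossBreakdown:
    """Components of one composite-loss evaluation."""

    l1_terms: np.ndarray  # per-paired-spike squared timing errors
    l2: float
    l3: float
    total: float
    active_case: str  # 'match' | 'underfire' | 'overfire'

    def to_dict(self) -> dict:
        return {
            "l1_terms": [float(x) for x in np.atleast_1d(self.l1_terms)],
            "l2": float(self.l2),
            "l3": float(self.l3),
            "total": float(self.total),
            "active_case": self.active_case,
        }


def loss_timing(t_actual: float, t_desired: float) -> float:
    """Squared timing error ``(t - t_hat)^2`` in ms^2."""
    return (t_actual - t_desired) ** 2


def window_start_index(t_ref: float, grid: SimulationGrid) -> int:
    """First sample index ``k`` with ``h k >= t_ref`` (clipped to the grid).

    A relative guard absorbs floating round-off when ``t_ref`` falls exactly
    on a grid time.
    """
    if t_ref <= 0:
        return 0
    k = int(np.ceil(t_ref / grid.h - 1e-9))
    return min(max(k, 0), grid.t_size)


def _membrane_of(traj, params: IzhikevichParams) -> np.ndarray:
    """Membrane-potential samples of a trajectory in either coordinate system."""
    if isinstance(traj, TransformedTrajectory):
        return np.asarray(phi(traj.y1, params), dtype=float)
    if isinstance(traj, Trajectory):
        return np.asarray(traj.v, dtype=float)
    return np.asarray(traj, dtype=float)


def loss_underfire(traj_v, spike_train: SpikeTrain, params: IzhikevichParams,
                   weights: LossWeights, grid: SimulationGrid) -> float:
    """Underfiring penalty: ``sum w1 (v_f - v(h k))^2`` after the last spike.

    The window runs over all grid samples ``k`` with ``h k >= t_N`` (the time
    of the last actual spike; from ``t = 0`` if there are none).
    """
    v = _membrane_of(traj_v, params)
    t_last = float(spike_train.times[-1]) if spike_train.count else 0.0
    start = window_start_index(t_last, grid)
    resid = params.v_peak - v[start:]
    return float(weights.w1 * np.sum(resid * resid))


def loss_overfire(traj_v, spike_train: SpikeTrain, target: SpikeTarget,
                  params: IzhikevichParams, weights: LossWeights,
                  grid: SimulationGrid, from_excess: bool = False) -> float:
    """Overfiring penalty: ``sum w2 (v(h k) - c)^2`` from the N_hat-th spike on.

    The window starts at the actual time of the ``N_hat``-th spike.  With
    ``from_excess`` it starts at the first excess spike (the
    ``N_hat + 1``-th) instead, a variant reading of the same penalty.
    """
    v = _membrane_of(traj_v, params)
    idx = target.count if from_excess else target.count - 1
    if idx < 0 or idx >= spike_train.count:
        t_ref = 0.0
    else:
        t_ref = float(spike_train.times[idx])
    start = window_start_index(t_ref, grid)
    resid = v[start:] - params.c
    return float(weights.w2 * np.sum(resid * resid))


def composite_loss(traj, spike_train: SpikeTrain, target: SpikeTarget,
                   params: IzhikevichParams, weights: LossWeights,
                   grid: SimulationGrid,
                   overfire_from_excess: bool = False) -> LossBreakdown:
    """Three-case composite spike-timing loss.

    ``traj`` may be a :class:`~spikesde.model.Trajectory`, a
    :class:`~spikesde.transform.TransformedTrajectory` (membrane read through
    ``phi``) or a plain array of membrane samples.
    """
    N, N_hat = spike_train.count, target.count
    n_paired = N_hat if N >= N_hat else N
    errors = spike_train.times[:n_paired] - target.times[:n_paired]
    l1_terms = np.square(errors)
    l1_sum = float(np.sum(l1_terms))
    if N == N_hat:
        return LossBreakdown(l1_terms=l1_terms, l2=0.0, l3=0.0,
                             total=l1_sum, active_case="match")
    if N < N_hat:
        l2 = loss_underfire(traj, spike_train, params, weights, grid)
        return LossBreakdown(l1_terms=l1_terms, l2=l2, l3=0.0,
                             total=l2 + l1_sum, active_case="underfire")
    l3 = loss_overfire(traj, spike_train, target, params, weights, grid,
                       from_excess=overfire_from_excess)
    return LossBreakdown(l1_terms=l1_terms, l2=0.0, l3=l3,
                         total=l3 + l1_sum, active_case="overfire")


def batch_loss(losses) -> float:
    """Arithmetic mean of composite-loss totals over a batch of sample paths."""
    totals = [
        loss.total if isinstance(loss, LossBreakdown) else float(loss)
        for loss in losses
    ]
    if not totals:
        raise ValueError("batch_loss requires a non-empty batch")
    return float(np.mean(totals))
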