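"""Learning the control current by gradient descent through the simulation.

The decision variable is the raw piecewise-constant waveform ``I_0..I_{t-1}``
(box-bounded).  Each epoch draws a fresh batch of Brownian paths, simulates
the neuron, evaluates the composite spike-timing loss per path, and
backpropagates through the *discrete* Euler-Maruyama recursion with the
noise frozen (discretize-then-optimize, common random numbers).

Two reverse-mode engines are provided, one per forward discretization:

* ``simulator="transformed"`` differentiates the reset-free recursion on
  ``(y1, y2)``.  Almost everywhere ``d phi/d y1 = 1`` and ``d psi/d y1 = 0``,
  so the adjoint recursion is plain.
* ``simulator="reset"`` (the training default) differentiates the biological
  reset recursion.  The reset assigns the constant ``c``, whose Jacobian in
  ``v`` is zero: gradients of a spike time naturally stop at the preceding
  reset, which decouples the inter-spike segments and — unlike the
  transformed path, whose overshoot carries a noise-dependent head start
  across spikes — matches the simulator used to evaluate trained controls.

Both engines agree with central finite differences (the independent oracle,
:func:`finite_difference_gradient`).

Rectifier slope: ``1`` where the raw drift is positive and ``0`` at exactly
zero.  Where the raw drift is negative the true derivative is zero, which
makes the whole gradient vanish identically when the drift is inactive
along the entire path (a resting neuron under the zero initial control) and
gradient descent can never start.  The backward pass therefore substitutes
a small surrogate slope there (``leak``, default 0.1) — the standard
surrogate-gradient device for spiking models.  Forward dynamics are
untouched; ``leak=0`` recovers the exact almost-everywhere gradient.

The default optimizer is a two-phase scheme (see :class:`TrainConfig`):
count acquisition by normalized gradient descent with momentum, then
timing refinement by damped per-spike Gauss-Newton steps computed from the
same reverse-mode pass.  Plain ``adam`` and ``sgd`` loops on the composite
gradient are available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .losses import (
    LossBreakdown,
    LossWeights,
    SpikeTarget,
    batch_loss,
    composite_loss,
    window_start_index,
)
from .model import (
    DEFAULT_CONTROL_BOUNDS,
    ControlSignal,
    IzhikevichParams,
    NoiseProcess,
    SimulationGrid,
    SpikeTrain,
)
from .transform import _crossings, simulate_transformed
from .model import simulate_reset

__all__ = [
    "TrainConfig",
    "TrainingTrace",
    "init_control",
    "clip_control",
    "train_control",
    "control_gradient",
    "finite_difference_gradient",
]

#: RNG substream tags; evaluation (experiments module) uses a disjoint tag.
TRAIN_STREAM = 1


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    ``epochs``, ``batch_size``, the 0.1 ms discretization and the +/-100
    control bounds follow the reference simulation settings.  The optimizer
    internals are free design choices; the default ``two_phase`` scheme is
    described in the module docstring.  ``beta`` is the training noise
    amplitude (also used at evaluation time by the experiment campaigns).
    """

    epochs: int = 100
    batch_size: int = 5
    learning_rate: float = 0.5  # step size for the adam/sgd optimizers
    optimizer: str = "two_phase"  # 'two_phase' | 'adam' | 'sgd'
    seed: int = 0
    beta: float = 1.0
    grid: SimulationGrid | None = None  # derived from the target horizon if None
    weights: LossWeights = field(default_factory=LossWeights)
    bounds: tuple[float, float] = DEFAULT_CONTROL_BOUNDS
    leak: float = 0.1  # surrogate rectifier slope where the drift is inactive
    init_v: float | None = None
    init_u: float | None = None
    overfire_from_excess: bool = False
    # --- two-phase optimizer ---
    acquisition_lr: float = 15.0  # mV per normalized acquisition step
    acquisition_momentum: float = 0.9
    stall_patience: int = 3  # epochs without count progress before boosting
    stall_boost: float = 1.7
    max_acquisition_lr: float = 150.0
    count_streak: int = 5  # matched-count epochs required to enter refinement
    refine_frac: float = 0.15  # fraction of epochs reserved for refinement
    refine_alpha: float = 0.5  # Gauss-Newton damping (annealed over the phase)
    refine_step_cap: float = 10.0  # per-spike step cap (mV)
    penalty_lr: float = 5.0  # normalized count-penalty step during refinement

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer not in ("two_phase", "adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.leak < 0:
            raise ValueError("leak must be >= 0")
        if not 0 < self.refine_frac < 1:
            raise ValueError("refine_frac must lie in (0, 1)")


@dataclass(frozen=True)
class TrainingTrace:
    """Per-epoch diagnostics of a training run."""

    batch_losses: np.ndarray  # (epochs,) mean composite loss over the batch
    spike_count_min: np.ndarray  # (epochs,)
    spike_count_max: np.ndarray  # (epochs,)
    final_control: ControlSignal
    refine_start: int | None = None  # epoch at which refinement began

    def __len__(self) -> int:
        return len(self.batch_losses)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.batch_losses)),
                "batch_loss": self.batch_losses,
                "min_spike_count": self.spike_count_min,
                "max_spike_count": self.spike_count_max,
            }
        )


def init_control(grid: SimulationGrid,
                 bounds: tuple[float, float] = DEFAULT_CONTROL_BOUNDS) -> ControlSignal:
    """All-zero control on the grid (the unbiased baseline)."""
    return ControlSignal.zeros(grid, bounds=bounds)


def clip_control(control, lower: float | None = None, upper: float | None = None):
    """Project control values onto the box ``[lower, upper]``.

    Accepts a :class:`ControlSignal` (its own bounds are used) or a plain
    array with explicit bounds; interior values pass through unchanged.
    """
    if isinstance(control, ControlSignal):
        lo = control.lower_bound if lower is None else lower
        hi = control.upper_bound if upper is None else upper
        return control.with_values(np.clip(control.values, lo, hi))
    if lower is None or upper is None:
        raise ValueError("explicit bounds are required for array input")
    return np.clip(np.asarray(control, dtype=float), lower, upper)


# ---------------------------------------------------------------------------
# Differentiable forward passes (batched)
# ---------------------------------------------------------------------------

def _rect_slope(raw: np.ndarray, leak: float) -> np.ndarray:
    return np.where(raw > 0, 1.0, np.where(raw < 0, leak, 0.0))


def _forward_transformed(params, grid, I, dW, beta, init_v, init_u, leak):
    """Reset-free forward; returns y1 samples, membrane read-out, slopes."""
    from .transform import mod_real

    B, t_size = dW.shape
    h = grid.h
    a, b, c, d = params.a, params.b, params.c, params.d
    period = params.period
    y1 = np.full(B, float(init_v))
    y2 = np.full(B, float(init_u))
    y1s = np.empty((B, t_size + 1))
    ps = np.empty((B, t_size + 1))
    gs = np.empty((B, t_size))
    y1s[:, 0] = y1
    for j in range(t_size):
        p = mod_real(y1 - c, period) + c
        s = y2 + d * (y1 - p) / period
        raw = 0.04 * p * p + 5.0 * p + 140.0 - s + I[j]
        ps[:, j] = p
        gs[:, j] = _rect_slope(raw, leak)
        y1 = y1 + np.maximum(raw, 0.0) * h + beta * dW[:, j]
        y2 = y2 + a * (b * p - s) * h
        y1s[:, j + 1] = y1
    ps[:, t_size] = mod_real(y1 - c, period) + c
    return y1s, ps, gs


def _forward_reset(params, grid, I, dW, beta, init_v, init_u, leak):
    """Reset-mode forward (overshoot discarded); stores what backprop needs."""
    B, t_size = dW.shape
    h = grid.h
    a, b, c, d = params.a, params.b, params.c, params.d
    vp = params.v_peak
    v = np.full(B, float(init_v))
    u = np.full(B, float(init_u))
    vs = np.empty((B, t_size + 1))
    us = np.empty((B, t_size + 1))
    gs = np.empty((B, t_size))
    spk = np.zeros((B, t_size), dtype=bool)
    vpre = np.empty((B, t_size))
    vs[:, 0] = v
    us[:, 0] = u
    for j in range(t_size):
        raw = 0.04 * v * v + 5.0 * v + 140.0 - u + I[j]
        gs[:, j] = _rect_slope(raw, leak)
        v_pre = v + np.maximum(raw, 0.0) * h + beta * dW[:, j]
        u_mid = u + a * (b * v - u) * h
        s = v_pre >= vp
        spk[:, j] = s
        vpre[:, j] = v_pre
        v = np.where(s, c, v_pre)
        u = u_mid + d * s
        vs[:, j + 1] = v
        us[:, j + 1] = u
    return vs, us, gs, spk, vpre


def _reset_spikes(vs_row, vpre_row, spk_row, grid, vp):
    """Interpolated crossing times and step indices of one reset-mode path."""
    times: list[float] = []
    steps: list[int] = []
    for j in np.nonzero(spk_row)[0]:
        v0, v1 = vs_row[j], vpre_row[j]
        times.append(j * grid.h + grid.h * float((vp - v0) / (v1 - v0)))
        steps.append(int(j))
    return times, steps


def _adjoint_sweep_reset(params, grid, vs, gs, spk, seeds_v, seeds_pre):
    """Vectorized adjoint of the reset recursion over rows.

    ``seeds_v`` (R, t+1) seeds the stored samples, ``seeds_pre`` (R, t) the
    pre-reset membrane value at spike steps.  At a spike step the stored
    sample is the constant ``c``, so the incoming membrane adjoint is
    replaced by the pre-reset seed; the recovery adjoint flows through.
    """
    R, t_size = gs.shape
    h, a, b = grid.h, params.a, params.b
    lam_v = seeds_v[:, t_size].copy()
    lam_u = np.zeros(R)
    grad = np.empty((R, t_size))
    for j in range(t_size - 1, -1, -1):
        lam_pre = np.where(spk[:, j], seeds_pre[:, j], lam_v)
        gj = gs[:, j]
        vj = vs[:, j]
        grad[:, j] = lam_pre * h * gj
        new_v = lam_pre * (1.0 + h * gj * (0.08 * vj + 5.0)) \
            + lam_u * (a * b * h) + seeds_v[:, j]
        new_u = -lam_pre * h * gj + lam_u * (1.0 - a * h)
        lam_v, lam_u = new_v, new_u
    return grad


def _adjoint_sweep_transformed(params, grid, ps, gs, seeds):
    """Vectorized adjoint of the reset-free recursion over rows."""
    R, t_size = gs.shape
    h, a, b = grid.h, params.a, params.b
    lam1 = seeds[:, t_size].copy()
    lam2 = np.zeros(R)
    grad = np.empty((R, t_size))
    for j in range(t_size - 1, -1, -1):
        gj = gs[:, j]
        pj = ps[:, j]
        grad[:, j] = lam1 * h * gj
        new1 = lam1 * (1.0 + h * gj * (0.08 * pj + 5.0)) + lam2 * (a * b * h) \
            + seeds[:, j]
        new2 = -lam1 * h * gj + lam2 * (1.0 - a * h)
        lam1, lam2 = new1, new2
    return grad


def _resolve_init(params, init_v, init_u):
    iv = params.c if init_v is None else init_v
    iu = params.b * params.c if init_u is None else init_u
    return float(iv), float(iu)


def _penalty_seed(breakdown, times, ps_row, params, target, weights, grid,
                  overfire_from_excess):
    """Adjoint seed of the active count penalty on the membrane samples."""
    t_size = len(ps_row) - 1
    seed = np.zeros(t_size + 1)
    N, N_hat = len(times), target.count
    if breakdown.active_case == "underfire":
        start = window_start_index(times[-1] if N else 0.0, grid)
        seed[start:] = -2.0 * weights.w1 * (params.v_peak - ps_row[start:])
    elif breakdown.active_case == "overfire":
        idx = N_hat if overfire_from_excess else N_hat - 1
        t_ref = times[idx] if 0 <= idx < N else 0.0
        start = window_start_index(t_ref, grid)
        seed[start:] = 2.0 * weights.w2 * (ps_row[start:] - params.c)
    return seed


def batch_loss_and_gradient(params: IzhikevichParams, grid: SimulationGrid,
                            I: np.ndarray, dW: np.ndarray, beta: float,
                            target: SpikeTarget, weights: LossWeights,
                            init_v: float | None = None,
                            init_u: float | None = None,
                            leak: float = 0.1,
                            overfire_from_excess: bool = False,
                            simulator: str = "reset"):
    """Mean composite loss over a batch of frozen noise paths and its gradient.

    ``dW`` is (batch, t_size).  Returns ``(loss, grad, breakdowns, counts)``.
    The case branch, spike pairing and penalty windows are constants of the
    forward pass; gradients flow through the trajectory samples and the
    interpolated spike times.
    """
    iv, iu = _resolve_init(params, init_v, init_u)
    B = dW.shape[0]
    t_size = grid.t_size
    breakdowns: list[LossBreakdown] = []
    counts = np.empty(B, dtype=int)

    if simulator == "transformed":
        y1s, ps, gs = _forward_transformed(params, grid, I, dW, beta, iv, iu, leak)
        seeds = np.zeros((B, t_size + 1))
        for i in range(B):
            crossings = _crossings(y1s[i], grid, params)
            times = [t for *_, t in crossings]
            train = SpikeTrain(times=np.asarray(times))
            bd = composite_loss(ps[i], train, target, params, weights, grid,
                                overfire_from_excess=overfire_from_excess)
            breakdowns.append(bd)
            counts[i] = train.count
            for (k, j, level, t) in crossings[:min(train.count, target.count)]:
                e = t - target.times[k - 1]
                delta = y1s[i, j + 1] - y1s[i, j]
                co = 2.0 * e * grid.h / (delta * delta)
                seeds[i, j] += co * (level - y1s[i, j + 1])
                seeds[i, j + 1] += -co * (level - y1s[i, j])
            seeds[i] += _penalty_seed(bd, times, ps[i], params, target,
                                      weights, grid, overfire_from_excess)
        grad = _adjoint_sweep_transformed(params, grid, ps, gs, seeds).mean(axis=0)
        return batch_loss(breakdowns), grad, breakdowns, counts

    if simulator != "reset":
        raise ValueError(f"unknown simulator {simulator!r}")
    vs, us, gs, spk, vpre = _forward_reset(params, grid, I, dW, beta, iv, iu, leak)
    seeds_v = np.zeros((B, t_size + 1))
    seeds_pre = np.zeros((B, t_size))
    for i in range(B):
        times, steps = _reset_spikes(vs[i], vpre[i], spk[i], grid, params.v_peak)
        train = SpikeTrain(times=np.asarray(times))
        bd = composite_loss(vs[i], train, target, params, weights, grid,
                            overfire_from_excess=overfire_from_excess)
        breakdowns.append(bd)
        counts[i] = train.count
        for k in range(min(train.count, target.count)):
            e = times[k] - target.times[k]
            j = steps[k]
            v0, v1 = vs[i, j], vpre[i, j]
            delta = v1 - v0
            co = 2.0 * e * grid.h / (delta * delta)
            seeds_v[i, j] += co * (params.v_peak - v1)
            seeds_pre[i, j] += -co * (params.v_peak - v0)
        seeds_v[i] += _penalty_seed(bd, times, vs[i], params, target,
                                    weights, grid, overfire_from_excess)
    grad = _adjoint_sweep_reset(params, grid, vs, gs, spk, seeds_v, seeds_pre)
    return batch_loss(breakdowns), grad.mean(axis=0), breakdowns, counts


def _spike_errors_and_jacobians(params, grid, target, I, dW, beta, weights,
                                init_v, init_u, leak, overfire_from_excess):
    """Batch-mean per-spike timing errors, their Jacobians ``dt_k/dI``, and
    the count-penalty gradient, all from one reset-mode forward pass."""
    iv, iu = _resolve_init(params, init_v, init_u)
    B = dW.shape[0]
    t_size = grid.t_size
    N_hat = target.count
    vs, us, gs, spk, vpre = _forward_reset(params, grid, I, dW, beta, iv, iu, leak)

    rows_v, rows_pre, rows_vs, rows_gs, rows_spk, row_key = [], [], [], [], [], []
    err_sum = np.zeros(N_hat)
    err_cnt = np.zeros(N_hat, dtype=int)
    pen_seed_rows = []
    counts = np.empty(B, dtype=int)
    total = 0.0
    for i in range(B):
        times, steps = _reset_spikes(vs[i], vpre[i], spk[i], grid, params.v_peak)
        train = SpikeTrain(times=np.asarray(times))
        bd = composite_loss(vs[i], train, target, params, weights, grid,
                            overfire_from_excess=overfire_from_excess)
        counts[i] = train.count
        total += bd.total
        for k in range(min(train.count, N_hat)):
            j = steps[k]
            v0, v1 = vs[i, j], vpre[i, j]
            delta = v1 - v0
            sv = np.zeros(t_size + 1)
            sp = np.zeros(t_size)
            sv[j] = grid.h * (params.v_peak - v1) / (delta * delta)
            sp[j] = -grid.h * (params.v_peak - v0) / (delta * delta)
            rows_v.append(sv)
            rows_pre.append(sp)
            row_key.append((i, k))
            err_sum[k] += times[k] - target.times[k]
            err_cnt[k] += 1
        pen = _penalty_seed(bd, times, vs[i], params, target, weights, grid,
                            overfire_from_excess)
        if np.any(pen):
            rows_v.append(pen)
            rows_pre.append(np.zeros(t_size))
            row_key.append((i, -1))

    pen_grad = np.zeros(t_size)
    jac = np.zeros((N_hat, t_size))
    if rows_v:
        idx = np.asarray([i for i, _ in row_key])
        grads = _adjoint_sweep_reset(
            params, grid, vs[idx], gs[idx], spk[idx],
            np.asarray(rows_v), np.asarray(rows_pre),
        )
        for r, (i, k) in enumerate(row_key):
            if k < 0:
                pen_grad += grads[r] / B
            else:
                jac[k] += grads[r]
    e_bar = np.where(err_cnt > 0, err_sum / np.maximum(err_cnt, 1), 0.0)
    jac /= np.maximum(err_cnt, 1)[:, None]
    return e_bar, err_cnt, jac, pen_grad, counts, total / B


def control_gradient(params: IzhikevichParams, target: SpikeTarget,
                     control: ControlSignal, noise: NoiseProcess,
                     weights: LossWeights, leak: float = 0.0,
                     init_v: float | None = None, init_u: float | None = None,
                     overfire_from_excess: bool = False,
                     simulator: str = "transformed") -> np.ndarray:
    """Reverse-mode gradient of the composite loss for one frozen noise path.

    ``leak=0`` gives the exact almost-everywhere gradient (rectifier slope 0
    wherever the drift is inactive), directly comparable to
    :func:`finite_difference_gradient` on the same simulator.
    """
    _, grad, _, _ = batch_loss_and_gradient(
        params, control.grid, control.values,
        noise.increments[None, :], noise.beta, target, weights,
        init_v, init_u, leak, overfire_from_excess, simulator=simulator,
    )
    return grad


def finite_difference_gradient(params: IzhikevichParams, target: SpikeTarget,
                               control: ControlSignal, noise: NoiseProcess,
                               weights: LossWeights, eps: float = 1e-4,
                               init_v: float | None = None,
                               init_u: float | None = None,
                               overfire_from_excess: bool = False,
                               simulator: str = "transformed") -> np.ndarray:
    """Central-difference gradient of the composite loss (frozen noise).

    The independent oracle for :func:`control_gradient`: each control value
    is perturbed by +/- ``eps`` with the Brownian increments held fixed and
    the loss re-evaluated through the full simulation.
    """
    if not eps > 0:
        raise ValueError("eps must be > 0")
    grid = control.grid

    def loss_of(values: np.ndarray) -> float:
        trial = ControlSignal(values, grid, lower_bound=-np.inf, upper_bound=np.inf)
        if simulator == "transformed":
            traj, train = simulate_transformed(
                params, trial, noise, init_v=init_v, init_u=init_u
            )
        else:
            traj, train = simulate_reset(
                params, trial, noise, init_v=init_v, init_u=init_u
            )
        return composite_loss(traj, train, target, params, weights, grid,
                              overfire_from_excess=overfire_from_excess).total

    base = control.values.astype(float)
    grad = np.empty_like(base)
    for j in range(len(base)):
        up = base.copy()
        up[j] += eps
        down = base.copy()
        down[j] -= eps
        grad[j] = (loss_of(up) - loss_of(down)) / (2.0 * eps)
    return grad


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _train_noise(config: TrainConfig, grid: SimulationGrid, epoch: int) -> np.ndarray:
    """Fresh batch of Brownian increments, seeded from (seed, epoch, path)."""
    dW = np.empty((config.batch_size, grid.t_size))
    for i in range(config.batch_size):
        rng = np.random.default_rng([TRAIN_STREAM, config.seed, epoch, i])
        dW[i] = rng.normal(0.0, np.sqrt(grid.h), size=grid.t_size)
    return dW


def train_control(params: IzhikevichParams, target: SpikeTarget,
                  config: TrainConfig) -> tuple[ControlSignal, TrainingTrace]:
    """Learn a control waveform that drives the neuron to the target times.

    The default two-phase optimizer first *acquires* the desired spike count
    (normalized gradient steps on the composite loss, with a step boost when
    the count stalls), then *refines* the timings (damped per-spike
    Gauss-Newton on the batch-mean errors, plus a small normalized step on
    the count penalty).  Refinement starts once the batch-median spike count
    has matched the target for ``count_streak`` consecutive epochs, or at
    the ``1 - refine_frac`` mark at the latest.  The run is bit-reproducible
    from ``config.seed``.

    Raises
    ------
    RuntimeError
        If the loss or gradient becomes non-finite (names the epoch).
    ValueError
        If the target horizon is inconsistent with the grid.
    """
    grid = config.grid or SimulationGrid.from_horizon(target.horizon)
    if target.horizon > grid.T + 0.5 * grid.h:
        raise ValueError(
            f"target horizon {target.horizon} ms exceeds the grid horizon {grid.T} ms"
        )
    lo, hi = config.bounds
    x = np.zeros(grid.t_size)
    losses = np.empty(config.epochs)
    cmin = np.empty(config.epochs, dtype=int)
    cmax = np.empty(config.epochs, dtype=int)

    if config.optimizer in ("adam", "sgd"):
        m = np.zeros_like(x)
        v = np.zeros_like(x)
        t = 0
        for epoch in range(config.epochs):
            dW = _train_noise(config, grid, epoch)
            loss, grad, _, counts = batch_loss_and_gradient(
                params, grid, x, dW, config.beta, target, config.weights,
                config.init_v, config.init_u, config.leak,
                config.overfire_from_excess,
            )
            _check_finite(loss, grad, epoch)
            if config.optimizer == "adam":
                t += 1
                m = 0.9 * m + 0.1 * grad
                v = 0.999 * v + 0.001 * grad * grad
                step = config.learning_rate * (m / (1 - 0.9 ** t)) / (
                    np.sqrt(v / (1 - 0.999 ** t)) + 1e-8
                )
            else:
                step = config.learning_rate * grad
            x = np.clip(x - step, lo, hi)
            losses[epoch] = loss
            cmin[epoch] = counts.min()
            cmax[epoch] = counts.max()
        control = ControlSignal(x, grid, lower_bound=lo, upper_bound=hi)
        trace = TrainingTrace(losses, cmin, cmax, control, refine_start=None)
        return control, trace

    # --- two-phase default ---
    momentum = np.zeros_like(x)
    refine_start: int | None = None
    streak = 0
    force_epoch = int(config.epochs * (1 - config.refine_frac))
    lr_phase = config.acquisition_lr
    best_median = -1
    since_progress = 0

    for epoch in range(config.epochs):
        dW = _train_noise(config, grid, epoch)
        if refine_start is None:
            loss, grad, _, counts = batch_loss_and_gradient(
                params, grid, x, dW, config.beta, target, config.weights,
                config.init_v, config.init_u, config.leak,
                config.overfire_from_excess,
            )
            _check_finite(loss, grad, epoch)
            median = int(np.median(counts))
            if median > best_median:
                best_median = median
                since_progress = 0
                lr_phase = config.acquisition_lr
            else:
                since_progress += 1
                if since_progress > config.stall_patience:
                    lr_phase = min(lr_phase * config.stall_boost,
                                   config.max_acquisition_lr)
                    since_progress = 0
            streak = streak + 1 if median == target.count else 0
            if streak >= config.count_streak or epoch >= force_epoch:
                refine_start = epoch
            mom = config.acquisition_momentum
            momentum = mom * momentum + (1 - mom) * grad
            norm = np.linalg.norm(momentum)
            if norm > 0:
                x = np.clip(x - lr_phase * momentum / norm, lo, hi)
        else:
            e_bar, e_cnt, jac, pen_grad, counts, loss = _spike_errors_and_jacobians(
                params, grid, target, x, dW, config.beta, config.weights,
                config.init_v, config.init_u, config.leak,
                config.overfire_from_excess,
            )
            _check_finite(loss, jac.ravel(), epoch)
            frac = (epoch - refine_start) / max(1, config.epochs - 1 - refine_start)
            alpha = config.refine_alpha * (0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * frac)))
            step = np.zeros_like(x)
            for k in range(target.count):
                if e_cnt[k] == 0:
                    continue
                nj2 = float(jac[k] @ jac[k])
                if nj2 < 1e-16:
                    continue
                delta = -alpha * e_bar[k] * jac[k] / nj2
                dmax = np.abs(delta).max()
                if dmax > config.refine_step_cap:
                    delta *= config.refine_step_cap / dmax
                step += delta
            pen_norm = np.linalg.norm(pen_grad)
            if pen_norm > 1e-12:
                step += -config.penalty_lr * pen_grad / pen_norm
            x = np.clip(x + step, lo, hi)
        losses[epoch] = loss
        cmin[epoch] = counts.min()
        cmax[epoch] = counts.max()

    control = ControlSignal(x, grid, lower_bound=lo, upper_bound=hi)
    trace = TrainingTrace(losses, cmin, cmax, control, refine_start=refine_start)
    return control, trace


def _check_finite(loss, grad, epoch: int) -> None:
    if not np.isfinite(loss) or not np.all(np.isfinite(grad)):
        raise RuntimeError(
            f"non-finite loss or gradient at epoch {epoch}; aborting training"
        )
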