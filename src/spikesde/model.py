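"""Noisy, rectified Izhikevich neuron model and its reset-based simulation.

The membrane potential ``v`` and recovery variable ``u`` follow

    dv/dt = max(0, 0.04 v^2 + 5 v + 140 - u + I) + beta dW,
    du/dt = a (b v - u),

with the after-spike reset ``v <- c``, ``u <- u + d`` whenever ``v`` reaches
the peak ``v_f``.  The rectifier on the deterministic part of ``dv/dt`` makes
the drift non-negative, which is what later allows the reset to be folded
into a reset-free change of coordinates (see :mod:`spikesde.transform`).

Units follow the conventional Izhikevich scaling: ``v`` in mV, time in ms,
``beta`` in mV/sqrt(ms).  The external current ``I(t)`` is piecewise constant
on a fixed grid and is the decision variable of the control problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "IzhikevichParams",
    "SimulationGrid",
    "NoiseProcess",
    "ControlSignal",
    "Trajectory",
    "SpikeTrain",
    "PRESETS",
    "preset_params",
    "initial_state",
    "drift_v",
    "drift_u",
    "apply_reset",
    "sample_noise",
    "simulate_reset",
]

#: Default spike peak (mV).  The classical Izhikevich formulation cuts the
#: upstroke at +30 mV; it is configurable on :class:`IzhikevichParams`.
DEFAULT_V_PEAK = 30.0

#: Box bounds on the control current, in the model's printed units.
DEFAULT_CONTROL_BOUNDS = (-100.0, 100.0)


@dataclass(frozen=True)
class IzhikevichParams:
    """Parameters ``(a, b, c, d)`` of one firing pattern plus the spike peak.

    Attributes
    ----------
    a : float
        Recovery time scale (1/ms); must be positive.
    b : float
        Sensitivity of the recovery variable to ``v`` (dimensionless).
    c : float
        After-spike reset potential (mV).
    d : float
        After-spike increment of the recovery variable.
    v_peak : float
        Spike peak / firing threshold ``v_f`` (mV); must exceed ``c``.
    pattern_name : str
        One of ``RS``, ``IB``, ``CH``, ``FS`` or ``custom``.
    """

    a: float
    b: float
    c: float
    d: float
    v_peak: float = DEFAULT_V_PEAK
    pattern_name: str = "custom"

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"recovery time scale a must be > 0, got {self.a}")
        if not self.v_peak > self.c:
            raise ValueError(
                f"spike peak v_peak={self.v_peak} must exceed reset potential c={self.c}"
            )

    @property
    def period(self) -> float:
        """Spacing ``v_f - c`` between consecutive spike levels (mV)."""
        return self.v_peak - self.c


#: The four canonical firing patterns: (a, b, c, d).
PRESETS: dict[str, tuple[float, float, float, float]] = {
    "RS": (0.02, 0.2, -65.0, 8.0),  # regular spiking
    "IB": (0.02, 0.2, -55.0, 4.0),  # intrinsically bursting
    "CH": (0.02, 0.2, -50.0, 2.0),  # chattering
    "FS": (0.1, 0.2, -65.0, 2.0),  # fast spiking
}


def preset_params(pattern_name: str, v_peak: float = DEFAULT_V_PEAK) -> IzhikevichParams:
    """Return the parameter set of a named firing pattern.

    Parameters
    ----------
    pattern_name : str
        One of ``RS`` (regular spiking), ``IB`` (intrinsically bursting),
        ``CH`` (chattering) or ``FS`` (fast spiking).
    v_peak : float, optional
        Spike peak; the conventional +30 mV by default.
    """
    try:
        a, b, c, d = PRESETS[pattern_name]
    except KeyError:
        valid = ", ".join(sorted(PRESETS))
        raise ValueError(
            f"unknown firing pattern {pattern_name!r}; valid patterns are: {valid}"
        ) from None
    return IzhikevichParams(a=a, b=b, c=c, d=d, v_peak=v_peak, pattern_name=pattern_name)


def initial_state(params: IzhikevichParams) -> tuple[float, float]:
    """Default initial condition ``(v0, u0) = (c, b c)`` of a pattern."""
    return params.c, params.b * params.c


@dataclass(frozen=True)
class SimulationGrid:
    """Uniform time grid with step ``h`` (ms) and ``t_size`` steps.

    Sample times are ``t_j = j h`` for ``j = 0..t_size``; the horizon is
    ``T = h * t_size``.
    """

    h: float
    t_size: int

    def __post_init__(self) -> None:
        if not self.h > 0:
            raise ValueError(f"step size h must be > 0, got {self.h}")
        if self.t_size < 1:
            raise ValueError(f"t_size must be >= 1, got {self.t_size}")

    @property
    def T(self) -> float:
        return self.h * self.t_size

    def times(self) -> np.ndarray:
        """All ``t_size + 1`` sample times."""
        return np.arange(self.t_size + 1) * self.h

    @staticmethod
    def from_horizon(T: float, h: float = 0.1) -> "SimulationGrid":
        """Grid covering ``[0, T]`` with step ``h`` (``T`` rounded to a step)."""
        return SimulationGrid(h=h, t_size=int(round(T / h)))


@dataclass(frozen=True)
class NoiseProcess:
    """Per-step Brownian increments ``dW_j ~ N(0, h)`` with their amplitude.

    The amplitude ``beta`` scales the increments at integration time, so one
    draw can be reused across noise levels (common random numbers).
    """

    grid: SimulationGrid
    beta: float
    increments: np.ndarray
    seed: object = None

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"noise amplitude beta must be >= 0, got {self.beta}")
        if len(self.increments) != self.grid.t_size:
            raise ValueError(
                f"expected {self.grid.t_size} increments, got {len(self.increments)}"
            )


def sample_noise(grid: SimulationGrid, beta: float, seed) -> NoiseProcess:
    """Draw the ``t_size`` Gaussian increments of a Wiener path on ``grid``.

    Each increment has mean zero and variance ``h``.  ``seed`` may be an int
    or a sequence of ints; the same seed reproduces the same increments
    bit-exactly.
    """
    if beta < 0:
        raise ValueError(f"noise amplitude beta must be >= 0, got {beta}")
    rng = np.random.default_rng(seed)
    increments = rng.normal(0.0, math.sqrt(grid.h), size=grid.t_size)
    return NoiseProcess(grid=grid, beta=beta, increments=increments, seed=seed)


@dataclass(frozen=True)
class ControlSignal:
    """Piecewise-constant input current ``I_j`` on ``[t_j, t_{j+1})``.

    Values are box-constrained to ``[lower_bound, upper_bound]``.
    """

    values: np.ndarray
    grid: SimulationGrid
    lower_bound: float = DEFAULT_CONTROL_BOUNDS[0]
    upper_bound: float = DEFAULT_CONTROL_BOUNDS[1]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.grid.t_size,):
            raise ValueError(
                f"control must have one value per grid interval "
                f"({self.grid.t_size}), got shape {values.shape}"
            )
        if self.lower_bound > self.upper_bound:
            raise ValueError("lower_bound must not exceed upper_bound")
        if values.min() < self.lower_bound or values.max() > self.upper_bound:
            raise ValueError(
                f"control values outside bounds [{self.lower_bound}, {self.upper_bound}]"
            )

    @staticmethod
    def zeros(grid: SimulationGrid, bounds=DEFAULT_CONTROL_BOUNDS) -> "ControlSignal":
        return ControlSignal(
            values=np.zeros(grid.t_size), grid=grid,
            lower_bound=bounds[0], upper_bound=bounds[1],
        )

    @staticmethod
    def constant(grid: SimulationGrid, value: float,
                 bounds=DEFAULT_CONTROL_BOUNDS) -> "ControlSignal":
        return ControlSignal(
            values=np.full(grid.t_size, float(value)), grid=grid,
            lower_bound=bounds[0], upper_bound=bounds[1],
        )

    def with_values(self, values: np.ndarray) -> "ControlSignal":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered firing times ``t_k`` (ms) of one simulation."""

    times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def count(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Trajectory:
    """Sampled ``(v, u)`` path of a reset-mode simulation."""

    grid: SimulationGrid
    v: np.ndarray
    u: np.ndarray
    control: ControlSignal
    noise: NoiseProcess

    def __post_init__(self) -> None:
        n = self.grid.t_size + 1
        if len(self.v) != n or len(self.u) != n:
            raise ValueError(f"trajectory must hold {n} samples of v and u")


# ---------------------------------------------------------------------------
# Vector field
# ---------------------------------------------------------------------------

def drift_v(v, u, I, params: IzhikevichParams | None = None):
    """Rectified membrane drift ``max(0, 0.04 v^2 + 5 v + 140 - u + I)``.

    Accepts scalars or arrays; always non-negative.  ``params`` is accepted
    for signature uniformity (the quadratic is pattern-independent).
    """
    raw = 0.04 * np.square(v) + 5.0 * v + 140.0 - u + I
    return np.maximum(0.0, raw)


def drift_u(v, u, params: IzhikevichParams):
    """Recovery drift ``a (b v - u)``."""
    return params.a * (params.b * v - u)


def apply_reset(v: float, u: float, params: IzhikevichParams,
                carry_overshoot: bool = False) -> tuple[float, float, bool]:
    """After-spike reset: if ``v >= v_peak`` then ``v <- c``, ``u <- u + d``.

    With ``carry_overshoot`` the excess ``v - v_peak`` accumulated within the
    discrete step is carried past the reset (``v <- c + (v - v_peak)``), which
    makes the discrete reset map coincide step-for-step with the reset-free
    transformed simulation.
    """
    if v >= params.v_peak:
        new_v = params.c + (v - params.v_peak) if carry_overshoot else params.c
        return new_v, u + params.d, True
    return v, u, False


# ---------------------------------------------------------------------------
# Forward simulation (Euler-Maruyama with reset)
# ---------------------------------------------------------------------------

def simulate_reset(
    params: IzhikevichParams,
    control: ControlSignal,
    noise: NoiseProcess,
    init_v: float | None = None,
    init_u: float | None = None,
    carry_overshoot: bool = False,
    dtype=np.float64,
) -> tuple[Trajectory, SpikeTrain]:
    """Integrate the reset-based stochastic model on the control's grid.

    Euler-Maruyama update per step ``j``::

        v_{j+1} = v_j + max(0, 0.04 v_j^2 + 5 v_j + 140 - u_j + I_j) h + beta dW_j
        u_{j+1} = u_j + a (b v_j - u_j) h

    followed by the threshold check and reset.  Each firing time is the
    linearly interpolated sub-step crossing of ``v_peak`` within the step in
    which the threshold is reached.  Noise enters only the ``v`` equation.

    Parameters
    ----------
    init_v, init_u : float, optional
        Initial state; defaults to the pattern's rest ``(c, b c)``.
    carry_overshoot : bool
        Carry the within-step overshoot past the reset (default off, the
        biological reset).  With it on, a single step may register several
        spikes if the increment exceeds ``v_peak - c``.
    dtype : numpy dtype
        Working precision; ``np.longdouble`` is used by the equivalence
        certification in :mod:`spikesde.transform`.

    Returns
    -------
    (Trajectory, SpikeTrain)
    """
    if control.grid != noise.grid:
        raise ValueError(
            f"control grid {control.grid} and noise grid {noise.grid} differ"
        )
    grid = control.grid
    h = dtype(grid.h)
    beta = dtype(noise.beta)
    a, b, c, d = dtype(params.a), dtype(params.b), dtype(params.c), dtype(params.d)
    v_peak = dtype(params.v_peak)
    period = dtype(params.v_peak) - dtype(params.c)

    v = dtype(params.c if init_v is None else init_v)
    u = dtype(params.b * params.c if init_u is None else init_u)
    I = control.values.astype(dtype)
    dW = noise.increments.astype(dtype)

    vs = np.empty(grid.t_size + 1, dtype=dtype)
    us = np.empty(grid.t_size + 1, dtype=dtype)
    vs[0], us[0] = v, u
    spike_times: list[float] = []

    for j in range(grid.t_size):
        raw = dtype(0.04) * v * v + dtype(5.0) * v + dtype(140.0) - u + I[j]
        f = raw if raw > 0 else dtype(0.0)
        v_pre = v + f * h + beta * dW[j]
        u_new = u + a * (b * v - u) * h
        t_j = j * grid.h
        if v_pre >= v_peak:
            if carry_overshoot:
                m = 0
                while v_pre - m * period >= v_peak:
                    level = v_peak + m * period
                    spike_times.append(
                        float(t_j + grid.h * float((level - v) / (v_pre - v)))
                    )
                    u_new = u_new + d
                    m += 1
                v_new = v_pre - m * period
            else:
                spike_times.append(
                    float(t_j + grid.h * float((v_peak - v) / (v_pre - v)))
                )
                u_new = u_new + d
                v_new = c
        else:
            v_new = v_pre
        v, u = v_new, u_new
        vs[j + 1], us[j + 1] = v, u

    traj = Trajectory(grid=grid, v=vs, u=us, control=control, noise=noise)
    return traj, SpikeTrain(times=np.asarray(spike_times))
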