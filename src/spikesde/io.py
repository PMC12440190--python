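"""Configuration handling, artifact persistence and test-fixture generation.

Machine-written artifacts are JSON (controls, spike trains), human-written
run configurations may be JSON or YAML, and tabular outputs (trajectories,
training traces, error statistics) are CSV.  Every artifact embeds the
resolved configuration hash and the seeds, so a run is reproducible from
its outputs alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .losses import LossWeights, SpikeTarget, composite_loss
from .model import (
    ControlSignal,
    SimulationGrid,
    SpikeTrain,
    Trajectory,
    preset_params,
    sample_noise,
    simulate_reset,
)
from .trainer import TrainConfig
from .transform import TransformedTrajectory, detect_spikes, phi, psi

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "save_control",
    "load_control",
    "save_spike_train",
    "trajectory_frame",
    "transformed_frame",
    "generate_fixtures",
]

#: RNG substream tag for fixture generation.
FIXTURE_STREAM = 3

_RUN_FIELDS = {
    "pattern", "desired_times", "beta", "h", "horizon", "epochs",
    "batch_size", "learning_rate", "optimizer", "seed", "w1", "w2",
    "lower_bound", "upper_bound", "n_trials", "out_dir",
}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved settings of one control-design run.

    Defaults follow the reference simulation settings (100 epochs, batch 5,
    h = 0.1 ms, horizon 5 ms with desired firings at 1.5 and 3.0 ms,
    control bounds +/-100).
    """

    pattern: str = "RS"
    desired_times: tuple = (1.5, 3.0)
    beta: float = 1.0
    h: float = 0.1
    horizon: float = 5.0
    epochs: int = 100
    batch_size: int = 5
    learning_rate: float = 0.5
    optimizer: str = "two_phase"
    seed: int = 0
    w1: float = 0.01
    w2: float = 0.01
    lower_bound: float = -100.0
    upper_bound: float = 100.0
    n_trials: int = 100
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.pattern not in ("RS", "IB", "CH", "FS", "custom"):
            raise ValueError(f"config key 'pattern': unknown pattern {self.pattern!r}")
        times = tuple(float(t) for t in self.desired_times)
        object.__setattr__(self, "desired_times", times)
        if list(times) != sorted(set(times)):
            raise ValueError(
                "config key 'desired_times': times must be strictly increasing"
            )
        if not self.h > 0:
            raise ValueError("config key 'h': step size must be > 0")
        if times and times[-1] >= self.horizon:
            raise ValueError(
                "config key 'horizon': must exceed the last desired time"
            )
        if self.beta < 0:
            raise ValueError("config key 'beta': must be >= 0")
        if self.epochs < 1:
            raise ValueError("config key 'epochs': must be >= 1")
        if self.batch_size < 1:
            raise ValueError("config key 'batch_size': must be >= 1")
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("config keys 'w1'/'w2': weights must be >= 0")

    # -- derived objects -------------------------------------------------
    def grid(self) -> SimulationGrid:
        return SimulationGrid.from_horizon(self.horizon, self.h)

    def target(self) -> SpikeTarget:
        return SpikeTarget(times=np.asarray(self.desired_times), horizon=self.horizon)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs,
            batch_size=self.batch_size,
            learning_rate=self.learning_rate,
            optimizer=self.optimizer,
            seed=self.seed,
            beta=self.beta,
            grid=self.grid(),
            weights=LossWeights(w1=self.w1, w2=self.w2),
            bounds=(self.lower_bound, self.upper_bound),
        )


def config_hash(config: RunConfig) -> str:
    """Short deterministic digest of a resolved configuration."""
    payload = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration.

    Omitted keys take the documented defaults; unknown keys are rejected
    with a message naming them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValueError(f"could not parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must hold a mapping of settings")
    data.pop("config_hash", None)  # embedded digest from save_config round-trips
    unknown = set(data) - _RUN_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    payload = asdict(config)
    payload["config_hash"] = config_hash(config)
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# Artifact persistence
# ---------------------------------------------------------------------------

def save_control(control: ControlSignal, path, metadata: dict | None = None) -> None:
    """Persist a control signal as JSON (bit-exact values via float repr)."""
    payload = {
        "grid": {"h": control.grid.h, "t_size": control.grid.t_size},
        "values": [float(v) for v in control.values],
        "bounds": [control.lower_bound, control.upper_bound],
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_control(path) -> tuple[ControlSignal, dict]:
    """Load a control signal; returns ``(control, metadata)``.

    Raises a ``ValueError`` naming the file on malformed input.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
        grid = SimulationGrid(h=payload["grid"]["h"], t_size=payload["grid"]["t_size"])
        lo, hi = payload["bounds"]
        control = ControlSignal(
            values=np.asarray(payload["values"], dtype=float),
            grid=grid, lower_bound=lo, upper_bound=hi,
        )
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupted control file {path}: {exc}") from exc
    return control, payload.get("metadata", {})


def save_spike_train(train: SpikeTrain, path, metadata: dict | None = None) -> None:
    payload = {
        "times": [float(t) for t in train.times],
        "count": train.count,
        "metadata": metadata or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Reset-mode trajectory as a tidy table (t, v, u, I, dW per grid point).

    The last row has no following interval, so its I and dW are NaN.
    """
    t_size = traj.grid.t_size
    return pd.DataFrame(
        {
            "t": traj.grid.times(),
            "v": np.asarray(traj.v, dtype=float),
            "u": np.asarray(traj.u, dtype=float),
            "I": np.append(traj.control.values, np.nan),
            "dW": np.append(traj.noise.increments, np.nan),
        }
    )


def transformed_frame(traj: TransformedTrajectory, params) -> pd.DataFrame:
    """Reset-free trajectory with the membrane/recovery read-outs."""
    return pd.DataFrame(
        {
            "t": traj.grid.times(),
            "y1": np.asarray(traj.y1, dtype=float),
            "y2": np.asarray(traj.y2, dtype=float),
            "phi_y1": np.asarray(phi(traj.y1, params), dtype=float),
            "psi": np.asarray(psi(traj.y1, traj.y2, params), dtype=float),
            "I": np.append(traj.control.values, np.nan),
        }
    )


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def _pulse_control(grid: SimulationGrid, start: float, stop: float,
                   amplitude: float) -> ControlSignal:
    values = np.zeros(grid.t_size)
    j0, j1 = int(round(start / grid.h)), int(round(stop / grid.h))
    values[j0:j1] = amplitude
    return ControlSignal(values, grid)


def generate_fixtures(seed: int = 0) -> dict:
    """Deterministic test inputs with independently known outcomes.

    Returns a dict with three groups:

    * ``pulse`` — an RS neuron under a hand-designed current pulse
      (60 units on [1, 2) ms, 5 ms horizon, no noise) together with its
      trajectory, its single spike time at h = 0.1 ms, and the reference
      spike time from an h = 0.001 ms integration of the same input.
    * ``crossings`` — synthetic transformed-potential ramps with exactly
      1, 2 and 3 level crossings for spike-detection tests.
    * ``loss_cases`` — hand-computable composite-loss scenarios, each with
      its expected value.
    """
    params = preset_params("RS")
    grid = SimulationGrid(h=0.1, t_size=50)
    control = _pulse_control(grid, 1.0, 2.0, 60.0)
    noise = sample_noise(grid, 0.0, [FIXTURE_STREAM, seed])
    traj, train = simulate_reset(params, control, noise)

    fine_grid = SimulationGrid(h=0.001, t_size=5000)
    fine_control = ControlSignal(np.repeat(control.values, 100), fine_grid)
    fine_noise = sample_noise(fine_grid, 0.0, [FIXTURE_STREAM, seed])
    _, fine_train = simulate_reset(params, fine_control, fine_noise)

    crossing_grid = SimulationGrid(h=0.1, t_size=10)
    period = params.period
    ramps = {}
    for n in (1, 2, 3):
        # linear ramp from rest crossing exactly n spike levels
        top = params.c + (n + 0.5) * period
        ramps[n] = np.linspace(params.c, top, crossing_grid.t_size + 1)

    loss_grid = SimulationGrid(h=1.0, t_size=4)
    underfire_v = np.array([-65.0, -65.0, -65.0, -60.0, -55.0])
    underfire_case = {
        "params": params,
        "grid": loss_grid,
        "v": underfire_v,
        "spike_train": SpikeTrain(times=np.array([2.0])),
        "target": SpikeTarget(times=np.array([2.0, 3.5]), horizon=4.0),
        "weights": LossWeights(w1=1.0, w2=1.0),
        # window from t=2.0: samples v = [-65, -60, -55], residuals 95, 90, 85
        "expected_total": 95.0 ** 2 + 90.0 ** 2 + 85.0 ** 2,  # = 24350
        "expected_case": "underfire",
    }
    return {
        "pulse": {
            "params": params,
            "control": control,
            "noise": noise,
            "trajectory": traj,
            "spike_train": train,
            "spike_time": float(train.times[0]) if train.count else None,
            "fine_spike_time": float(fine_train.times[0]) if fine_train.count else None,
        },
        "crossings": {"grid": crossing_grid, "params": params, "ramps": ramps},
        "loss_cases": {"underfire": underfire_case},
    }
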