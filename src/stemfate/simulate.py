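"""Euler-Maruyama simulation of the coupled order-parameter/noise system.

The order parameter receives additive white noise of amplitude ``sigma``
standing in for finite-population fluctuations (sigma -> 0 in the
thermodynamic limit); the feedback equation for xi is deterministic:

    m_{k+1}  = m_k + drift(m_k, xi_k) dt + sigma sqrt(dt) z_k
    xi_{k+1} = xi_k + G (m_k^2 - M^2) dt

With ``sigma = 0`` the scheme reduces to forward Euler on the deterministic
flow, which is how phase portraits (spirals, limit cycles) are produced.

Reproducibility: each trajectory of an ensemble draws from its own
``numpy.random.Generator`` seeded by ``SeedSequence(master_seed,
spawn_key=(index,))`` — a counter-based split, so trajectory ``i`` is
bit-identical regardless of ensemble size or execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from . import _kernels
from .models import FeedbackParams, ModelSpec, SystemState, drift, feedback_rate

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "Ensemble",
    "sigma_from_population",
    "step_em",
    "simulate",
    "simulate_ensemble",
]


def sigma_from_population(N: float, *, c: float = 1.0, exponent: float = 0.5) -> float:
    """Noise amplitude for a population of N cells: sigma = c / N**exponent.

    The exponent is configurable (1/2 for central-limit scaling of additive
    fluctuations, 1 for strict inverse proportionality).
    """
    if N <= 0:
        raise ValueError(f"population size must be positive, got {N}")
    return c / N**exponent


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings for single trajectories and ensembles.

    ``record_stride`` stores every k-th step (default 100, i.e. every 0.1
    time units at dt = 1e-3) to keep 1000-trajectory ensembles in memory.
    ``xi_floor_policy`` is "none" (xi may go negative; the drift stays
    well-defined) or "clamp" (floor xi at 0, since it models a noise
    strength).
    """

    t_final: float
    dt: float = 1e-3
    sigma: float = 0.0
    n_traj: int = 1
    master_seed: int = 0
    record_stride: int = 100
    initial_state: SystemState = field(default_factory=lambda: SystemState(0.001, 1.5))
    xi_floor_policy: str = "none"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.t_final < self.dt:
            raise ValueError(f"t_final must be >= dt, got {self.t_final}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.n_traj < 1:
            raise ValueError(f"n_traj must be >= 1, got {self.n_traj}")
        if self.record_stride < 1:
            raise ValueError(f"record_stride must be >= 1, got {self.record_stride}")
        if self.xi_floor_policy not in ("none", "clamp"):
            raise ValueError(f"xi_floor_policy must be 'none' or 'clamp', got {self.xi_floor_policy!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_final / self.dt))


@dataclass(frozen=True)
class Trajectory:
    """One recorded path: uniform times, m(t), xi(t), and the stream seed."""

    times: np.ndarray
    m: np.ndarray
    xi: np.ndarray
    seed: int

    @property
    def states(self) -> np.ndarray:
        """(n, 2) array of recorded (m, xi) pairs."""
        return np.column_stack([self.m, self.xi])

    def state_at(self, index: int) -> SystemState:
        return SystemState(float(self.m[index]), float(self.xi[index]))

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class Ensemble:
    trajectories: tuple[Trajectory, ...]
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    @property
    def m_matrix(self) -> np.ndarray:
        """(n_traj, n_times) matrix of order-parameter paths."""
        return np.stack([t.m for t in self.trajectories])

    @property
    def times(self) -> np.ndarray:
        return self.trajectories[0].times


def step_em(
    state: SystemState,
    spec: ModelSpec,
    fb: FeedbackParams,
    dt: float,
    sigma: float,
    z: float,
    *,
    xi_floor_policy: str = "none",
) -> SystemState:
    """One Euler-Maruyama step; ``z`` is a standard-normal draw."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    m = state.m + drift(state.m, state.xi, spec) * dt + sigma * np.sqrt(dt) * z
    xi = state.xi + feedback_rate(state.m, fb) * dt
    if xi_floor_policy == "clamp" and xi < 0.0:
        xi = 0.0
    if not (np.isfinite(m) and np.isfinite(xi)):
        raise RuntimeError(f"non-finite state after one step from {state}")
    return SystemState(float(m), float(xi))


def _trajectory_seed(master_seed: int, index: int) -> tuple[np.random.Generator, int]:
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    fingerprint = int(ss.generate_state(1, dtype=np.uint64)[0])
    return np.random.default_rng(ss), fingerprint


def _run_one(spec: ModelSpec, fb: FeedbackParams, config: SimulationConfig, index: int) -> Trajectory:
    nsteps = config.n_steps
    rng, fingerprint = _trajectory_seed(config.master_seed, index)
    if config.sigma > 0.0:
        noise = rng.standard_normal(nsteps)
    else:
        noise = np.empty(0)
    m_rec, xi_rec, abort = _kernels.em_path(
        config.initial_state.m,
        config.initial_state.xi,
        spec.alpha,
        spec.beta,
        spec.gamma,
        fb.G,
        fb.M,
        config.dt,
        nsteps,
        config.sigma,
        noise,
        config.record_stride,
        config.xi_floor_policy == "clamp",
    )
    if abort >= 0:
        raise RuntimeError(
            f"trajectory {index} (seed {fingerprint}) became non-finite at step {abort} "
            f"(t={abort * config.dt:.6g})"
        )
    times = np.arange(len(m_rec)) * config.dt * config.record_stride
    return Trajectory(times=times, m=m_rec, xi=xi_rec, seed=fingerprint)


def simulate(spec: ModelSpec, fb: FeedbackParams, config: SimulationConfig) -> Trajectory:
    """Integrate a single trajectory (requires ``config.n_traj == 1``)."""
    if config.n_traj != 1:
        raise ValueError("simulate() is for single trajectories; use simulate_ensemble()")
    return _run_one(spec, fb, config, 0)


def simulate_ensemble(spec: ModelSpec, fb: FeedbackParams, config: SimulationConfig) -> Ensemble:
    """Integrate ``config.n_traj`` independent trajectories.

    Bitwise reproducible for a given ``master_seed``; per-trajectory streams
    are independent splits, so results do not depend on ensemble ordering.
    """
    trajectories = tuple(_run_one(spec, fb, config, i) for i in range(config.n_traj))
    return Ensemble(trajectories=trajectories, config=config)
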