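"""Run configuration and text-based writers/readers.

All outputs are plain delimited text with a YAML metadata header embedded in
``#``-prefixed comment lines, so every file round-trips through this module
and carries enough metadata to re-run the producing command.  Numeric output
uses full double precision (%.17g).  Data files contain no timestamps:
repeated runs with the same seed are byte-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .models import FeedbackParams, ModelSpec, SystemState
from .simulate import SimulationConfig, Trajectory, sigma_from_population

__all__ = [
    "RunConfig",
    "write_trajectory",
    "read_trajectory",
    "write_density_grid",
    "read_density_grid",
    "write_report",
    "read_report",
]

ANALYSES = ("trajectories", "density", "quasipotential", "fates", "cycle", "switching")


@dataclass(frozen=True)
class RunConfig:
    """Complete description of one reproducible run.

    The model is either a preset (``model`` in {model1, model2, model3}) or
    an explicit coefficient triple; the noise amplitude is either ``sigma``
    directly or derived from a population size ``N`` via
    sigma = sigma_scale / N**sigma_exponent.
    """

    model: str | None = None
    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    G: float = 0.05
    M: float = 0.5
    sigma: float | None = None
    N: float | None = None
    sigma_scale: float = 1.0
    sigma_exponent: float = 0.5
    dt: float = 1e-3
    t_final: float = 100.0
    n_traj: int = 1
    seed: int = 0
    m0: float = 0.001
    xi0: float = 1.5
    record_stride: int = 100
    xi_floor_policy: str = "none"
    outdir: str | None = None
    analyses: tuple[str, ...] = ("trajectories", "density")
    schema_version: int = 1

    def __post_init__(self) -> None:
        for a in self.analyses:
            if a not in ANALYSES:
                raise ValueError(f"unknown analysis {a!r}; choose from {ANALYSES}")
        if self.sigma is not None and self.N is not None:
            raise ValueError("give sigma or N, not both")
        # fail fast: build every validated object once
        spec = self.model_spec()
        self.feedback()
        self.sim_config()
        from .models import admissible_upper_bound

        bound = admissible_upper_bound(spec)
        if self.M >= bound:
            raise ValueError(
                f"M={self.M} outside admissible range: requires M < {bound:.6g} "
                f"to keep the equilibrium noise level non-negative"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a config file; keyword overrides (e.g. CLI flags) win."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        version = raw.pop("schema_version", 1)
        if version != 1:
            raise ValueError(f"unsupported config schema_version {version}")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["analyses"] = list(self.analyses)
        return d

    def model_spec(self) -> ModelSpec:
        if self.model is not None:
            if (self.alpha, self.beta, self.gamma) != (None, None, None):
                raise ValueError("give a model preset or explicit coefficients, not both")
            return ModelSpec.from_preset(self.model)
        if None in (self.alpha, self.beta, self.gamma):
            raise ValueError("need a model preset or all of alpha/beta/gamma")
        return ModelSpec(self.alpha, self.beta, self.gamma)

    def feedback(self) -> FeedbackParams:
        return FeedbackParams(self.G, self.M)

    def effective_sigma(self) -> float:
        if self.N is not None:
            return sigma_from_population(self.N, c=self.sigma_scale, exponent=self.sigma_exponent)
        return self.sigma if self.sigma is not None else 0.0

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            t_final=self.t_final,
            dt=self.dt,
            sigma=self.effective_sigma(),
            n_traj=self.n_traj,
            master_seed=self.seed,
            record_stride=self.record_stride,
            initial_state=SystemState(self.m0, self.xi0),
            xi_floor_policy=self.xi_floor_policy,
        )


def _pyify(obj: Any) -> Any:
    """Convert numpy scalars/arrays to plain Python for YAML round-trips."""
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_pyify(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_meta_header(fh, meta: dict) -> None:
    text = yaml.safe_dump(_pyify(meta), sort_keys=True).rstrip("\n")
    for line in text.split("\n"):
        fh.write(f"# {line}\n")


def _read_meta_header(path: Path) -> tuple[dict, int]:
    meta_lines = []
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("# "):
                meta_lines.append(line[2:])
                n += 1
            elif line.startswith("#"):
                meta_lines.append(line[1:])
                n += 1
            else:
                break
    meta = yaml.safe_load("".join(meta_lines)) if meta_lines else {}
    return meta or {}, n


def write_trajectory(path: str | Path, traj: Trajectory, meta: dict | None = None) -> None:
    """Write a (t, m, xi) table with YAML header; the seed is stored in the header."""
    meta = dict(meta or {})
    meta["seed"] = int(traj.seed)
    path = Path(path)
    with open(path, "w") as fh:
        _write_meta_header(fh, meta)
        fh.write("t\tm\txi\n")
        for t, m, xi in zip(traj.times, traj.m, traj.xi):
            fh.write(f"{t:.17g}\t{m:.17g}\t{xi:.17g}\n")


def read_trajectory(path: str | Path) -> tuple[Trajectory, dict]:
    path = Path(path)
    meta, skip = _read_meta_header(path)
    df = pd.read_csv(path, sep="\t", skiprows=skip, float_precision="round_trip")
    traj = Trajectory(
        times=df["t"].to_numpy(),
        m=df["m"].to_numpy(),
        xi=df["xi"].to_numpy(),
        seed=int(meta.get("seed", -1)),
    )
    return traj, meta


def write_density_grid(path: str | Path, m_edges, t_nodes, values, meta: dict | None = None) -> None:
    """Write a (time x m-bin) matrix: header row of bin centers, first column t.

    Works for both density and quasi-potential grids (NaN marks masked bins).
    """
    m_edges = np.asarray(m_edges, dtype=float)
    centers = 0.5 * (m_edges[:-1] + m_edges[1:])
    meta = dict(meta or {})
    meta["m_edges"] = m_edges
    path = Path(path)
    with open(path, "w") as fh:
        _write_meta_header(fh, meta)
        fh.write("t\t" + "\t".join(f"{c:.17g}" for c in centers) + "\n")
        for t, row in zip(t_nodes, values):
            fh.write(f"{t:.17g}\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_density_grid(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Return (m_edges, t_nodes, values, meta)."""
    path = Path(path)
    meta, skip = _read_meta_header(path)
    df = pd.read_csv(path, sep="\t", skiprows=skip, float_precision="round_trip")
    t_nodes = df["t"].to_numpy()
    values = df.drop(columns="t").to_numpy()
    m_edges = np.asarray(meta.pop("m_edges"), dtype=float)
    return m_edges, t_nodes, values, meta


def write_report(path: str | Path, report: dict) -> None:
    Path(path).write_text(yaml.safe_dump(_pyify(report), sort_keys=True))


def read_report(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
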