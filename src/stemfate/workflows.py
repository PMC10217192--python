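"""High-level runs tying the analysis modules into reproducible outputs.

Each workflow takes a validated :class:`~stemfate.io.RunConfig`, runs the
relevant computations, and (optionally) writes text outputs whose headers
embed the full configuration.  Data files carry no timestamps, so repeated
runs with the same seed produce byte-identical files; wall-clock information
goes to the per-run log only.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bifurcation import critical_noise, equilibrium_branches, ground_state
from .io import (
    RunConfig,
    write_density_grid,
    write_report,
    write_trajectory,
)
from .models import SystemState, equilibria
from .observables import (
    fate_fractions,
    limit_cycle_summary,
    pdf_over_time,
    quasi_potential,
    switching_report,
    default_basins,
)
from .simulate import simulate_ensemble
from .stability import admissible_M_range, classify, hopf_point, jacobian

__all__ = ["run_stability", "run_bifurcation", "run_simulation"]

log = logging.getLogger("stemfate")


def _meta(config: RunConfig) -> dict:
    # outdir is implied by the file's own location; dropping it keeps outputs
    # byte-identical across runs that differ only in destination
    d = config.to_dict()
    d.pop("outdir", None)
    return {"config": d, "stemfate_version": __version__}


def run_stability(config: RunConfig, *, assess_hopf_character: bool = False) -> dict:
    """Equilibria, Jacobian diagnostics, classification, Hopf point, bounds.

    Deterministic; returns a plain dict (also writable via write_report).
    """
    spec = config.model_spec()
    fb = config.feedback()
    report: dict = _meta(config)
    report["admissible_M_upper_bound"] = admissible_M_range(spec)
    eqs = equilibria(spec, fb)
    eq_entries = []
    for p in eqs:
        state_jac = jacobian(spec, fb, SystemState(p.m_star, p.xi_star))
        eq_entries.append(
            {
                "branch": p.branch_label,
                "m_star": p.m_star,
                "xi_star": p.xi_star,
                "jacobian": state_jac.entries.tolist(),
                "trace": state_jac.trace,
                "det": state_jac.det,
                "eigenvalues": [
                    {"re": ev.real, "im": ev.imag} for ev in state_jac.eigenvalues
                ],
                "classification": classify(state_jac),
            }
        )
    report["equilibria"] = eq_entries
    if fb.G > 0:
        h = hopf_point(spec, fb.G, assess_character=assess_hopf_character)
        report["hopf"] = {
            "exists": h.exists,
            "Mc": h.Mc,
            "branch": h.branch,
            "character": h.character,
        }
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(out / "stability_report.yaml", report)
    return report


def run_bifurcation(config: RunConfig, xi_grid=None) -> dict:
    """Branch table, critical-noise table, and ground-state table over a xi grid."""
    spec = config.model_spec()
    if xi_grid is None:
        xi_grid = np.round(np.arange(0.0, 1.5 + 1e-9, 0.01), 10)
    xi_grid = np.asarray(xi_grid, dtype=float)
    if len(xi_grid) == 0:
        raise ValueError("empty xi grid")
    branches = equilibrium_branches(spec, xi_grid).records
    cn = critical_noise(spec)
    critical = pd.DataFrame(
        [
            {"quantity": "xi_c", "value": cn.xi_c},
            *([{"quantity": "xi_transition", "value": cn.xi_transition}] if cn.xi_transition is not None else []),
            *([{"quantity": "xi_saddle", "value": cn.xi_saddle}] if cn.xi_saddle is not None else []),
        ]
    )
    ground = pd.DataFrame(
        [
            {"xi": xi, "m_ground": m}
            for xi in xi_grid
            for m in ground_state(spec, float(xi))
        ]
    )
    result = {
        "branches": branches,
        "critical": critical,
        "transition_order": cn.transition_order,
        "ground": ground,
    }
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        meta = _meta(config)
        for name, df in (("branches", branches), ("critical", critical), ("ground", ground)):
            path = out / f"{name}.tsv"
            with open(path, "w") as fh:
                from .io import _write_meta_header

                _write_meta_header(fh, meta)
                df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    return result


def run_simulation(config: RunConfig) -> dict:
    """Simulate an ensemble and write the requested analyses.

    Writes into ``config.outdir``: trajectory tables, density grid,
    quasi-potential grid, fate fractions, limit-cycle and switching reports,
    as listed in ``config.analyses``.  On abort, partial outputs are removed.
    """
    spec = config.model_spec()
    fb = config.feedback()
    sim_cfg = config.sim_config()
    t0 = time.perf_counter()
    ens = simulate_ensemble(spec, fb, sim_cfg)
    log.info("simulated %d trajectories in %.2f s", len(ens), time.perf_counter() - t0)
    if np.any(np.stack([t.xi for t in ens]) < 0):
        log.warning("xi went negative during the run (xi_floor_policy=%s)", sim_cfg.xi_floor_policy)

    manifest: dict = {"files": [], "n_traj": len(ens)}
    if not config.outdir:
        manifest["ensemble"] = ens
        return manifest
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    meta = _meta(config)
    try:
        if "trajectories" in config.analyses:
            for i, traj in enumerate(ens):
                p = out / f"trajectory_{i:04d}.tsv"
                write_trajectory(p, traj, meta)
                written.append(p)
        grid = None
        if "density" in config.analyses or "quasipotential" in config.analyses:
            grid = pdf_over_time(ens)
        if "density" in config.analyses:
            p = out / "density.tsv"
            write_density_grid(p, grid.m_edges, grid.t_nodes, grid.density, meta)
            written.append(p)
        if "quasipotential" in config.analyses:
            q = quasi_potential(grid)
            p = out / "quasipotential.tsv"
            write_density_grid(p, q.m_edges, q.t_nodes, q.phi, meta)
            written.append(p)
        if "fates" in config.analyses:
            eqs = equilibria(spec, fb)
            fr = fate_fractions(ens, eqs, radius=0.1, t_eval=float(ens.times[-1]))
            p = out / "fate_fractions.yaml"
            write_report(p, {**meta, "t_eval": float(ens.times[-1]), "radius": 0.1, "fractions": fr})
            written.append(p)
        if "cycle" in config.analyses:
            lc = limit_cycle_summary(ens.trajectories[0])
            p = out / "limit_cycle.yaml"
            write_report(
                p,
                {
                    **meta,
                    "is_cycle": lc.is_cycle,
                    "period": lc.period,
                    "m_amplitude": lc.m_amplitude,
                    "orientation": lc.orientation,
                    "mean_point": list(lc.mean_point) if lc.mean_point else None,
                    "status": lc.status,
                },
            )
            written.append(p)
        if "switching" in config.analyses:
            eqs = equilibria(spec, fb)
            basins = default_basins([0.0] + [p_.m_star for p_ in eqs])
            sw = switching_report(ens.trajectories[0], basins)
            p = out / "switching.yaml"
            write_report(
                p,
                {
                    **meta,
                    "basins": {k: list(v) for k, v in basins.items()},
                    "transition_count": sw.transition_count,
                    "dwell_times": sw.dwell_times,
                },
            )
            written.append(p)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    manifest["files"] = [str(p) for p in written]
    return manifest
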