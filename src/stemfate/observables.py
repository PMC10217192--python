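"""Trajectory and ensemble observables.

Turns simulated paths into the quantities used to characterize cell-fate
dynamics: the time-resolved probability density P(m, t) across an ensemble,
the quasi-potential Phi = -ln P (an empirical Waddington landscape), fate
fractions at the attractors, limit-cycle summaries (period, amplitude,
orientation in the (m, xi) plane), and switching/dwell statistics between
labeled basins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .models import EquilibriumPoint
from .simulate import Ensemble, Trajectory

__all__ = [
    "DensityGrid",
    "QuasiPotentialGrid",
    "LimitCycleSummary",
    "SwitchingReport",
    "pdf_over_time",
    "quasi_potential",
    "fate_fractions",
    "limit_cycle_summary",
    "switching_report",
    "default_basins",
]

#: default histogram support and resolution for the order parameter
DEFAULT_M_EDGES = np.linspace(-1.5, 1.5, 202)


@dataclass(frozen=True)
class DensityGrid:
    """Time-resolved histogram density P(m, t); rows are time nodes."""

    m_edges: np.ndarray
    t_nodes: np.ndarray
    density: np.ndarray  # shape (len(t_nodes), len(m_edges) - 1)

    @property
    def m_centers(self) -> np.ndarray:
        return 0.5 * (self.m_edges[:-1] + self.m_edges[1:])


@dataclass(frozen=True)
class QuasiPotentialGrid:
    """Phi = -ln P on occupied bins; empty bins are NaN-masked, never imputed."""

    m_edges: np.ndarray
    t_nodes: np.ndarray
    phi: np.ndarray

    @property
    def m_centers(self) -> np.ndarray:
        return 0.5 * (self.m_edges[:-1] + self.m_edges[1:])


@dataclass(frozen=True)
class LimitCycleSummary:
    is_cycle: bool
    period: float | None = None
    m_amplitude: float | None = None
    orientation: str | None = None  # "clockwise" | "counterclockwise"
    mean_point: tuple[float, float] | None = None
    status: str = "ok"  # "ok" | "undetermined"


@dataclass(frozen=True)
class SwitchingReport:
    """Hysteretic basin labels per recorded time, transitions, dwell times."""

    labels: np.ndarray  # object array of basin labels (None before first entry)
    transition_count: int
    dwell_times: dict[str, list[float]]

    def mean_dwell(self, label: str) -> float:
        d = self.dwell_times.get(label, [])
        return float(np.mean(d)) if d else 0.0


def _nearest_indices(times: np.ndarray, t_nodes: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(times, t_nodes)
    idx = np.clip(idx, 0, len(times) - 1)
    left = np.clip(idx - 1, 0, len(times) - 1)
    use_left = np.abs(times[left] - t_nodes) < np.abs(times[idx] - t_nodes)
    return np.where(use_left, left, idx)


def pdf_over_time(
    ens: Ensemble,
    m_edges: np.ndarray | None = None,
    t_nodes: np.ndarray | None = None,
) -> DensityGrid:
    """Normalized histogram of m across trajectories at each time node.

    Normalization is per time node: sum(P) * dm = 1.
    """
    if len(ens) == 0:
        raise ValueError("empty ensemble")
    if m_edges is None:
        m_edges = DEFAULT_M_EDGES
    m_edges = np.asarray(m_edges, dtype=float)
    times = ens.times
    if t_nodes is None:
        t_nodes = times
    t_nodes = np.atleast_1d(np.asarray(t_nodes, dtype=float))
    if t_nodes.min() < times[0] - 1e-12 or t_nodes.max() > times[-1] + 1e-12:
        raise ValueError("t_nodes outside the recorded trajectory range")
    M = ens.m_matrix
    idx = _nearest_indices(times, t_nodes)
    density = np.empty((len(t_nodes), len(m_edges) - 1))
    for k, i in enumerate(idx):
        density[k], _ = np.histogram(M[:, i], bins=m_edges, density=True)
    return DensityGrid(m_edges=m_edges, t_nodes=t_nodes, density=density)


def quasi_potential(grid: DensityGrid) -> QuasiPotentialGrid:
    """Quasi-potential Phi(m, t) = -ln P(m, t), masked where P = 0."""
    with np.errstate(divide="ignore"):
        phi = np.where(grid.density > 0.0, -np.log(grid.density), np.nan)
    return QuasiPotentialGrid(m_edges=grid.m_edges, t_nodes=grid.t_nodes, phi=phi)


def fate_fractions(
    ens: Ensemble,
    eq_points: Sequence[EquilibriumPoint],
    radius: float,
    t_eval: float,
) -> dict[str, float]:
    """Fraction of trajectories within ``radius`` (in m) of each attractor.

    Trajectories near no attractor count as "undecided"; ties go to the
    nearest attractor.  Fractions sum to 1.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    times = ens.times
    if not (times[0] - 1e-12 <= t_eval <= times[-1] + 1e-12):
        raise ValueError("t_eval outside the recorded trajectory range")
    i = int(_nearest_indices(times, np.array([t_eval]))[0])
    m_vals = ens.m_matrix[:, i]
    targets = {p.branch_label: p.m_star for p in eq_points}
    counts = dict.fromkeys(targets, 0)
    undecided = 0
    for m in m_vals:
        dists = {lbl: abs(m - mt) for lbl, mt in targets.items()}
        lbl, d = min(dists.items(), key=lambda kv: kv[1])
        if d <= radius:
            counts[lbl] += 1
        else:
            undecided += 1
    n = len(m_vals)
    out = {lbl: c / n for lbl, c in counts.items()}
    out["undecided"] = undecided / n
    return out


def limit_cycle_summary(
    traj: Trajectory,
    transient_fraction: float = 0.5,
    *,
    amplitude_threshold: float = 1e-3,
    period_cv_max: float = 0.05,
) -> LimitCycleSummary:
    """Detect and summarize a limit cycle on a (preferably deterministic) path.

    After discarding the initial ``transient_fraction`` of the horizon, a
    cycle is declared when the m oscillation amplitude exceeds
    ``amplitude_threshold``, successive maxima are regularly spaced (period
    coefficient of variation below ``period_cv_max``), and the amplitude is
    stationary rather than decaying (a converging spiral rings at a regular
    period too, but its amplitude shrinks).  Orientation is the sign of the
    signed area accumulated along the (m, xi) loop: positive area =
    counterclockwise.
    """
    if not (0.0 <= transient_fraction < 1.0):
        raise ValueError(f"transient_fraction must be in [0, 1), got {transient_fraction}")
    start = int(len(traj) * transient_fraction)
    m = traj.m[start:]
    xi = traj.xi[start:]
    t = traj.times[start:]
    if len(m) < 8:
        return LimitCycleSummary(is_cycle=False, status="undetermined")

    tail = slice(int(len(m) * 0.75), None)
    amp_tail = 0.5 * (m[tail].max() - m[tail].min())
    peaks, _ = find_peaks(m, prominence=amplitude_threshold / 2.0)
    if len(peaks) < 5:
        if amp_tail <= amplitude_threshold:
            return LimitCycleSummary(is_cycle=False, status="ok")  # converged
        return LimitCycleSummary(is_cycle=False, status="undetermined")

    spacings = np.diff(t[peaks])
    period = float(np.mean(spacings))
    cv = float(np.std(spacings) / period) if period > 0 else np.inf
    head = slice(0, int(len(m) * 0.25))
    amp_head = 0.5 * (m[head].max() - m[head].min())
    stationary = amp_head <= 0.0 or amp_tail / max(amp_head, 1e-300) > 0.8
    if not (amp_tail > amplitude_threshold and cv < period_cv_max and stationary):
        return LimitCycleSummary(is_cycle=False, status="ok")

    # one full cycle span at the end for area/means
    loop = slice(peaks[-4], peaks[-1] + 1)
    area = 0.5 * float(
        np.sum(m[loop][:-1] * xi[loop][1:] - m[loop][1:] * xi[loop][:-1])
    )
    orientation = "counterclockwise" if area > 0 else "clockwise"
    return LimitCycleSummary(
        is_cycle=True,
        period=period,
        m_amplitude=float(amp_tail),
        orientation=orientation,
        mean_point=(float(np.mean(m[loop])), float(np.mean(xi[loop]))),
        status="ok",
    )


def default_basins(attractor_ms: Sequence[float], *, width_factor: float = 0.3) -> dict[str, tuple[float, float]]:
    """Disjoint m-intervals around attractors, half-width = width_factor * min spacing."""
    ms = sorted(attractor_ms)
    if len(ms) < 2:
        raise ValueError("need at least two attractors to define basins")
    spacing = min(b - a for a, b in zip(ms, ms[1:]))
    h = width_factor * spacing
    return {f"basin_{m:+.3g}": (m - h, m + h) for m in ms}


def switching_report(
    traj: Trajectory,
    basins: Mapping[str, tuple[float, float]],
) -> SwitchingReport:
    """Label each recorded time with a basin, hysteretically.

    The label changes only when m enters a different labeled interval
    (Schmitt-trigger assignment): in the unlabeled gaps the previous label is
    kept, which suppresses chatter at basin boundaries.  Dwell times are the
    durations of consecutive same-label runs, in trajectory time units.
    """
    items = list(basins.items())
    for i, (la, (lo_a, hi_a)) in enumerate(items):
        if lo_a >= hi_a:
            raise ValueError(f"basin {la!r} has empty interval ({lo_a}, {hi_a})")
        for lb, (lo_b, hi_b) in items[i + 1:]:
            if lo_a < hi_b and lo_b < hi_a:
                raise ValueError(f"basins {la!r} and {lb!r} overlap")

    labels = np.empty(len(traj), dtype=object)
    current: str | None = None
    for k, m in enumerate(traj.m):
        for lbl, (lo, hi) in items:
            if lo <= m <= hi:
                current = lbl
                break
        labels[k] = current

    dt_rec = float(traj.times[1] - traj.times[0]) if len(traj) > 1 else 0.0
    transitions = 0
    dwell: dict[str, list[float]] = {lbl: [] for lbl, _ in items}
    run_label, run_len = None, 0
    for lbl in labels:
        if lbl == run_label:
            run_len += 1
            continue
        if run_label is not None:
            dwell[run_label].append(run_len * dt_rec)
            if lbl is not None:
                transitions += 1
        run_label, run_len = lbl, 1
    if run_label is not None and run_len:
        dwell[run_label].append(run_len * dt_rec)
    return SwitchingReport(labels=labels, transition_count=transitions, dwell_times=dwell)
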