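"""Fixed-noise analysis of the Landau potential (feedback off).

With xi held fixed, the order parameter relaxes down dV/dm and the model
reduces to a one-dimensional gradient system.  This module computes:

* equilibrium branches m(xi) with stability flags (bifurcation diagram);
* the critical noise values: xi_c where the pluripotent state m = 0 loses
  linear stability, the saddle-node point where nonzero branches appear as
  double roots, and the phase-transition point where the global minimum of
  V (the ground state) shifts — continuously (second order) or
  discontinuously (first order);
* ground states (global minimizers of V among stationary points);
* quasi-static hysteresis sweeps, relaxing m by damped gradient flow while
  xi is ramped (phenotypic-memory loops).

For the presets the exact branch formulas are used (model 1:
m = +-sqrt(1-xi); model 2: m^2 = 0.5 +- sqrt(1.25 - xi); model 3:
m = 0.5 +- sqrt(1.25 - xi)); custom coefficient sets fall back to
polynomial root finding, and the two routes are cross-checked in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .models import ModelSpec, drift_dm, potential, xi_star

__all__ = [
    "BranchSet",
    "CriticalNoiseSet",
    "HysteresisResult",
    "equilibrium_branches",
    "critical_noise",
    "ground_state",
    "hysteresis_sweep",
]


@dataclass(frozen=True)
class BranchSet:
    """Equilibrium branches on a noise grid, as tidy records.

    ``records`` columns: xi, label, m, stable.  Labels follow the field's
    naming: m0 (pluripotent), m_plus/m_minus (outer branches),
    mu_plus/mu_minus (inner unstable branches of the subcritical scenario);
    custom specs get generic branch_k labels ordered by m.
    """

    records: pd.DataFrame

    def at(self, xi: float, *, tol: float = 1e-12) -> pd.DataFrame:
        r = self.records
        return r[np.abs(r["xi"] - xi) <= tol]


@dataclass(frozen=True)
class CriticalNoiseSet:
    """Critical noise levels of the fixed-noise system.

    xi_c: loss of linear stability of m = 0 (always 1: the linearization of
    the drift at the origin is (1 - xi) m).
    xi_saddle: double-root (saddle-node) location, if any.
    xi_transition: ground-state shift; transition_order is "first" when the
    shift is discontinuous (a nonzero degenerate minimum exists) and
    "second" when the new minima grow continuously out of m = 0.
    """

    xi_c: float
    xi_saddle: float | None
    xi_transition: float | None
    transition_order: str | None


def _real_roots(coeffs: np.ndarray, *, tol: float = 1e-9) -> list[float]:
    coeffs = np.trim_zeros(np.asarray(coeffs, dtype=float), "f")
    if len(coeffs) < 2:
        return []
    return sorted(float(r.real) for r in np.roots(coeffs) if abs(r.imag) < tol)


def _nonzero_roots(spec: ModelSpec, xi: float) -> list[float]:
    """Real roots of drift(m, xi)/m = (1-xi) - alpha m - beta m^2 - gamma m^4."""
    return _real_roots([-spec.gamma, 0.0, -spec.beta, -spec.alpha, 1.0 - xi])


def _preset_branches(spec: ModelSpec, xi: float) -> list[tuple[str, float]]:
    out: list[tuple[str, float]] = [("m0", 0.0)]
    if spec.name == "model1":
        if xi <= 1.0:
            r = math.sqrt(1.0 - xi)
            out += [("m_plus", r), ("m_minus", -r)]
    elif spec.name == "model2":
        if xi <= 1.25:
            s = math.sqrt(1.25 - xi)
            r = math.sqrt(0.5 + s)
            out += [("m_plus", r), ("m_minus", -r)]
            if 0.5 - s >= 0.0:
                q = math.sqrt(0.5 - s)
                out += [("mu_plus", q), ("mu_minus", -q)]
    elif spec.name == "model3":
        if xi <= 1.25:
            s = math.sqrt(1.25 - xi)
            out += [("m_plus", 0.5 + s), ("m_minus", 0.5 - s)]
    return out


def equilibrium_branches(spec: ModelSpec, xi_grid) -> BranchSet:
    """All real equilibria of the fixed-noise drift on a grid of xi values."""
    xi_grid = np.atleast_1d(np.asarray(xi_grid, dtype=float))
    if len(xi_grid) == 0:
        raise ValueError("xi grid is empty")
    if np.any(xi_grid < 0):
        raise ValueError("xi grid values must be >= 0")
    rows = []
    for xi in xi_grid:
        if spec.name in ("model1", "model2", "model3"):
            branches = _preset_branches(spec, float(xi))
        else:
            ms = [0.0] + [m for m in _nonzero_roots(spec, float(xi)) if abs(m) > 1e-12]
            branches = [("m0" if m == 0.0 else f"branch_{i}", m) for i, m in enumerate(sorted(ms))]
        for label, m in branches:
            rows.append(
                {
                    "xi": float(xi),
                    "label": label,
                    "m": m,
                    "stable": bool(drift_dm(m, float(xi), spec) < 0.0),
                }
            )
    return BranchSet(records=pd.DataFrame(rows))


def _saddle_node_xi(spec: ModelSpec) -> float | None:
    """Largest xi >= 0 where drift has a nonzero double root.

    Double-root condition on g(m) = drift/m: g = 0 and g' = 0, i.e. m is a
    nonzero critical point of g and xi = xi*(m).
    """
    # g'(m) = -alpha - 2 beta m - 4 gamma m^3
    crit = _real_roots([-4.0 * spec.gamma, 0.0, -2.0 * spec.beta, -spec.alpha])
    cand = [xi_star(spec, m) for m in crit if abs(m) > 1e-12]
    cand = [xi for xi in cand if xi >= 0.0]
    return max(cand) if cand else None


def _first_order_transition(spec: ModelSpec) -> tuple[float, float] | None:
    """Nonzero degenerate-minimum point: V = 0 and dV/dm = 0 at m != 0.

    Eliminating (1 - xi) via the stationarity condition reduces V = 0 to
    alpha/6 + beta m/4 + gamma m^3/3 = 0; each real root m gives a candidate
    xi = xi*(m), kept if it is a local minimum with xi >= 0.  Returns
    (xi, m) with the largest xi (the shift met first when lowering noise).
    """
    roots = _real_roots([-spec.gamma / 3.0, 0.0, -spec.beta / 4.0, -spec.alpha / 6.0])
    best = None
    for m in roots:
        if abs(m) < 1e-12:
            continue
        xi = xi_star(spec, m)
        if xi < 0.0:
            continue
        if drift_dm(m, xi, spec) > -1e-12:  # not a strict minimum of V
            continue
        if abs(potential(m, xi, spec)) > 1e-9:
            continue
        if best is None or xi > best[0]:
            best = (xi, m)
    return best


def critical_noise(spec: ModelSpec) -> CriticalNoiseSet:
    """Critical noise levels: stability loss of m0, saddle-node, transition.

    Presets: model 1 -> (1, none, 1, second); model 2 -> (1, 5/4, 19/16,
    first); model 3 -> (1, 5/4, 11/9, first).
    """
    xi_c = 1.0  # linearization at m = 0 is (1 - xi) m for every coefficient set
    xi_saddle = _saddle_node_xi(spec)
    fo = _first_order_transition(spec)
    if fo is not None:
        xi_transition, order = fo[0], "first"
    else:
        # no coexistence point: the ordered branch grows continuously out of
        # m = 0 at xi_c (pitchfork), so the ground-state shift is continuous
        xi_transition, order = xi_c, "second"
    return CriticalNoiseSet(
        xi_c=xi_c, xi_saddle=xi_saddle, xi_transition=xi_transition, transition_order=order
    )


def ground_state(spec: ModelSpec, xi: float, *, tie_tol: float = 1e-9) -> list[float]:
    """Global minimizers of V(., xi) among stationary points.

    Degenerate (tied) minima are all returned — at a first-order transition
    point the pluripotent and differentiated states coexist.
    """
    if xi < 0:
        raise ValueError(f"xi must be >= 0, got {xi}")
    ms = [0.0] + [m for m in _nonzero_roots(spec, xi) if abs(m) > 1e-12]
    vals = np.array([potential(m, xi, spec) for m in ms])
    vmin = vals.min()
    return sorted(m for m, v in zip(ms, vals) if v - vmin <= tie_tol)


@dataclass(frozen=True)
class HysteresisResult:
    """Quasi-static sweep path and detected jumps.

    ``path`` columns: xi, m (settled).  ``jumps``: records with the xi at
    which the settled branch changed discontinuously, and m before/after.
    """

    path: pd.DataFrame
    jumps: pd.DataFrame


def hysteresis_sweep(
    spec: ModelSpec,
    xi_schedule,
    m_init: float,
    *,
    flow_dt: float = 0.02,
    residual_tol: float = 1e-8,
    max_iter: int = 5_000_000,
    kick: float = 1e-6,
    jump_threshold: float = 0.2,
) -> HysteresisResult:
    """Relax m to the nearest stable branch at each xi of a monotone ramp.

    At every schedule point the deterministic gradient flow is integrated to
    steady state (|drift| < residual_tol) starting from the previously
    settled value, nudged by ``kick`` so the invariant line m = 0 cannot trap
    the sweep when the pluripotent state is unstable.  Jumps larger than
    ``jump_threshold`` in |m| between consecutive points are reported.
    """
    xi_schedule = np.asarray(xi_schedule, dtype=float)
    if len(xi_schedule) == 0:
        raise ValueError("empty xi schedule")
    if np.any(xi_schedule < 0):
        raise ValueError("xi schedule values must be >= 0")
    m = float(m_init)
    settled = []
    for xi in xi_schedule:
        start = m + (kick if m >= 0.0 else -kick)
        m_new = float(
            _kernels.relax_fixed_xi(
                start, float(xi), spec.alpha, spec.beta, spec.gamma,
                flow_dt, residual_tol, max_iter,
            )
        )
        if not np.isfinite(m_new):
            raise RuntimeError(f"gradient flow diverged at xi={xi}")
        settled.append(m_new)
        m = m_new
    path = pd.DataFrame({"xi": xi_schedule, "m": settled})
    dm = np.abs(np.diff(settled))
    idx = np.nonzero(dm > jump_threshold)[0]
    jumps = pd.DataFrame(
        {
            "xi_before": xi_schedule[idx],
            "xi_after": xi_schedule[idx + 1],
            "m_before": np.asarray(settled)[idx],
            "m_after": np.asarray(settled)[idx + 1],
        }
    )
    return HysteresisResult(path=path, jumps=jumps)
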