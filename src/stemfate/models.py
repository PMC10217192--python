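"""Core model definitions: Landau potential, drift, noise feedback, and equilibria.

The model describes a stem-cell population by a single order parameter ``m``
(the population-average cell state; ``m = 0`` is pluripotent, ``m != 0`` is
differentiated) coupled to the intrinsic gene-expression noise ``xi``, which
plays the role temperature plays in Landau theory but is itself dynamical.

The free-energy ansatz is the polynomial

    V(m, xi) = -(1 - xi)/2 m^2 + alpha/3 m^3 + beta/4 m^4 + gamma/6 m^6

and the order parameter relaxes down its gradient,

    dm/dt = -dV/dm = (1 - xi) m - alpha m^2 - beta m^3 - gamma m^5,

while a negative feedback drives the noise toward the set-point ``M``:

    dxi/dt = G (m^2 - M^2).

Three named coefficient presets reproduce the canonical scenarios:

* ``model1`` (0, 1, 0):  supercritical pitchfork, second-order transition;
* ``model2`` (0, -1, 1): double saddle-node + first-order transition,
  hysteresis, and a supercritical Hopf bifurcation under feedback;
* ``model3`` (-1, 1, 0): asymmetric wells, transcritical + saddle-node,
  first-order transition, Hopf bifurcation on the ``m > 0`` branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import optimize

__all__ = [
    "ModelSpec",
    "FeedbackParams",
    "SystemState",
    "EquilibriumPoint",
    "MODEL_PRESETS",
    "potential",
    "drift",
    "drift_dm",
    "feedback_rate",
    "xi_star",
    "admissible_upper_bound",
    "equilibria",
    "find_equilibria_numeric",
]

#: Coefficient triples (alpha, beta, gamma) of the named models.
MODEL_PRESETS: dict[str, tuple[float, float, float]] = {
    "model1": (0.0, 1.0, 0.0),
    "model2": (0.0, -1.0, 1.0),
    "model3": (-1.0, 1.0, 0.0),
}


def _check_finite(**vals: float) -> None:
    for name, v in vals.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Coefficients (alpha, beta, gamma) of the Landau polynomial.

    Arbitrary reals are accepted provided the potential is bounded below
    (leading even coefficient positive); the three presets pin the published
    models.  A preset ``name`` must match its coefficient triple exactly.
    """

    alpha: float
    beta: float
    gamma: float
    name: str = "custom"

    def __post_init__(self) -> None:
        _check_finite(alpha=self.alpha, beta=self.beta, gamma=self.gamma)
        if self.gamma < 0:
            raise ValueError("gamma < 0: potential unbounded below")
        if self.gamma == 0 and self.beta <= 0:
            raise ValueError(
                "potential unbounded below: need gamma > 0 or (gamma == 0 and beta > 0)"
            )
        if self.name != "custom":
            preset = MODEL_PRESETS.get(self.name)
            if preset is None:
                raise ValueError(f"unknown model name {self.name!r}")
            if preset != (self.alpha, self.beta, self.gamma):
                raise ValueError(
                    f"name {self.name!r} requires coefficients {preset}, "
                    f"got ({self.alpha}, {self.beta}, {self.gamma})"
                )

    @classmethod
    def from_preset(cls, name: str) -> "ModelSpec":
        if name not in MODEL_PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(MODEL_PRESETS)}")
        a, b, g = MODEL_PRESETS[name]
        return cls(a, b, g, name=name)

    @property
    def is_symmetric(self) -> bool:
        """True when V is even in m (alpha == 0)."""
        return self.alpha == 0.0


@dataclass(frozen=True)
class FeedbackParams:
    """Noise-feedback control parameters: gain G >= 0 and set-point M >= 0.

    G = 0 is the fixed-noise limit (feedback off), useful for gradient-flow
    checks; the equilibrium analyses require G > 0.
    """

    G: float
    M: float

    def __post_init__(self) -> None:
        _check_finite(G=self.G, M=self.M)
        if self.G < 0:
            raise ValueError(f"feedback gain G must be >= 0, got {self.G}")
        if self.M < 0:
            raise ValueError(f"set-point M must be >= 0, got {self.M}")


@dataclass(frozen=True)
class SystemState:
    """State of the coupled system: order parameter m and intrinsic noise xi."""

    m: float
    xi: float

    def __post_init__(self) -> None:
        _check_finite(m=self.m, xi=self.xi)


@dataclass(frozen=True)
class EquilibriumPoint:
    m_star: float
    xi_star: float
    branch_label: str  # "E_plus" | "E_minus"


def potential(m, xi, spec: ModelSpec):
    """Landau potential V(m, xi).  Accepts scalars or numpy arrays."""
    _check_finite(m=m, xi=xi)
    m = np.asarray(m, dtype=float) if not np.isscalar(m) else m
    return (
        -(1.0 - xi) / 2.0 * m**2
        + spec.alpha / 3.0 * m**3
        + spec.beta / 4.0 * m**4
        + spec.gamma / 6.0 * m**6
    )


def drift(m, xi, spec: ModelSpec):
    """Deterministic drift of m: -dV/dm = (1-xi)m - alpha m^2 - beta m^3 - gamma m^5."""
    _check_finite(m=m, xi=xi)
    return (1.0 - xi) * m - spec.alpha * m**2 - spec.beta * m**3 - spec.gamma * m**5


def drift_dm(m, xi, spec: ModelSpec):
    """Analytic d(drift)/dm, used for branch stability and Jacobians."""
    return (1.0 - xi) - 2.0 * spec.alpha * m - 3.0 * spec.beta * m**2 - 5.0 * spec.gamma * m**4


def feedback_rate(m, fb: FeedbackParams):
    """Rate of change of the intrinsic noise: G (m^2 - M^2); zero iff |m| = M."""
    _check_finite(m=m)
    return fb.G * (m**2 - fb.M**2)


def xi_star(spec: ModelSpec, m: float) -> float:
    """Equilibrium noise level at order parameter m, from drift(m, xi*) = 0 (m != 0)."""
    return 1.0 - spec.alpha * m - spec.beta * m**2 - spec.gamma * m**4


def admissible_upper_bound(spec: ModelSpec) -> float:
    """Supremum of set-points M for which both equilibria keep xi* >= 0.

    Computed as the smallest positive root of xi*(+M) = 0 or xi*(-M) = 0.
    Returns ``math.inf`` if neither polynomial has a positive root (cannot
    occur for a bounded-below spec, where the leading coefficient of xi*(M)
    is negative; kept for completeness).
    """
    best = math.inf
    for sgn in (+1.0, -1.0):
        # xi*(sgn*M) = -gamma M^4 - beta M^2 - sgn*alpha M + 1 as a poly in M
        coeffs = [-spec.gamma, 0.0, -spec.beta, -sgn * spec.alpha, 1.0]
        while coeffs and coeffs[0] == 0.0:
            coeffs = coeffs[1:]
        if len(coeffs) < 2:
            continue
        for r in np.roots(coeffs):
            if abs(r.imag) < 1e-12 and r.real > 1e-12:
                best = min(best, float(r.real))
    return best


def equilibria(spec: ModelSpec, fb: FeedbackParams, *, tol: float = 1e-12) -> list[EquilibriumPoint]:
    """Closed-form equilibria E+/- = (+-M, xi*) of the coupled system.

    The feedback nullcline forces |m| = M; the drift nullcline then gives
    xi* = 1 - alpha m - beta m^2 - gamma m^4 at m = +-M.  Raises if either
    branch would need xi* < 0 (M at or beyond the admissible bound).
    """
    M = fb.M
    points = []
    for sgn, label in ((+1.0, "E_plus"), (-1.0, "E_minus")):
        m = sgn * M
        xi = xi_star(spec, m)
        if xi < -tol:
            bound = admissible_upper_bound(spec)
            raise ValueError(
                f"M={M} outside admissible range: branch {label} has xi*={xi:.6g} < 0; "
                f"requires M < {bound:.6g}"
            )
        points.append(EquilibriumPoint(m, max(xi, 0.0), label))
    # contract check: both nullclines vanish
    for p in points:
        assert abs(drift(p.m_star, p.xi_star, spec)) <= 1e-10 * max(1.0, M)
        assert abs(feedback_rate(p.m_star, fb)) <= 1e-12
    return points


def find_equilibria_numeric(
    spec: ModelSpec,
    fb: FeedbackParams,
    *,
    m_grid: Iterable[float] | None = None,
    xi_grid: Iterable[float] | None = None,
    tol: float = 1e-10,
) -> list[tuple[float, float]]:
    """Brute-force 2-D root finding on (drift, feedback_rate) = (0, 0).

    Independent of the closed forms in :func:`equilibria`; runs a damped
    Newton iteration (scipy ``fsolve``) from a grid of starts and deduplicates
    converged roots with xi >= 0.  Used as the cross-check oracle in tests.
    """
    if m_grid is None:
        m_grid = np.linspace(-1.5, 1.5, 13)
    if xi_grid is None:
        xi_grid = np.linspace(0.0, 2.0, 9)

    def fun(v):
        m, xi = v
        return [drift(m, xi, spec), feedback_rate(m, fb)]

    roots: list[tuple[float, float]] = []
    for m0 in m_grid:
        for x0 in xi_grid:
            sol, info, ier, _ = optimize.fsolve(fun, [m0, x0], full_output=True, xtol=1e-13)
            if ier != 1:
                continue
            m, xi = float(sol[0]), float(sol[1])
            if xi < -tol or max(abs(r) for r in fun([m, xi])) > tol:
                continue
            if fb.G > 0 and abs(abs(m) - fb.M) > 1e-8:
                continue  # fsolve stalled on the m=0 drift line, not a joint root
            if not any(abs(m - rm) < 1e-8 and abs(xi - rx) < 1e-8 for rm, rx in roots):
                roots.append((m, max(xi, 0.0)))
    return sorted(roots)
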