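"""Linear stability of the coupled system: Jacobians, Poincare classification,
Hopf detection, and admissible set-point ranges.

At an equilibrium E+/- = (+-M, xi*) the Jacobian is

    J = [ d(drift)/dm   -m ]
        [ 2 G m          0 ]

with trace T = d(drift)/dm evaluated at the equilibrium and determinant
Delta = 2 G m^2 > 0 for m != 0.  The eigenvalues are the roots of
lambda^2 - T lambda + Delta = 0, i.e. lambda = [T +- sqrt(T^2 - 4 Delta)]/2,
and the equilibrium type follows from the sign pattern of (T, Delta,
T^2 - 4 Delta) — the trace-determinant (Poincare) diagram.

A Hopf bifurcation occurs where T crosses zero with Delta > 0.  Whether it
is supercritical (a small stable limit cycle exists just below the critical
set-point Mc) is decided numerically by simulating on both sides of Mc,
rather than by computing the first Lyapunov coefficient.
"""

from __future__ import annotations

import cmath
from dataclasses import dataclass

import numpy as np

from .models import (
    FeedbackParams,
    ModelSpec,
    SystemState,
    admissible_upper_bound,
    drift_dm,
    xi_star,
)

__all__ = [
    "JacobianReport",
    "STABILITY_LABELS",
    "HopfResult",
    "jacobian",
    "eigenvalues",
    "classify",
    "hopf_point",
    "admissible_M_range",
]

STABILITY_LABELS = (
    "stable_node",
    "stable_spiral",
    "stable_degenerate_node",
    "unstable_node",
    "unstable_spiral",
    "saddle",
    "center_candidate",
    "nonhyperbolic",
)

#: sign tolerance for trace/determinant/discriminant zero tests
SIGN_TOL = 1e-10


@dataclass(frozen=True)
class JacobianReport:
    entries: np.ndarray  # 2x2
    trace: float
    det: float
    eigenvalues: tuple[complex, complex]

    @classmethod
    def from_matrix(cls, J: np.ndarray) -> "JacobianReport":
        J = np.asarray(J, dtype=float)
        tr = float(J[0, 0] + J[1, 1])
        det = float(J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0])
        return cls(entries=J, trace=tr, det=det, eigenvalues=_eig_from_trace_det(tr, det))


def _eig_from_trace_det(trace: float, det: float) -> tuple[complex, complex]:
    disc = cmath.sqrt(trace * trace - 4.0 * det)
    return ((trace + disc) / 2.0, (trace - disc) / 2.0)


def jacobian(spec: ModelSpec, fb: FeedbackParams, state: SystemState) -> JacobianReport:
    """Jacobian of (dm/dt, dxi/dt) at an arbitrary state.

    Entries: (1,1) = d(drift)/dm, (1,2) = d(drift)/dxi = -m,
    (2,1) = d(feedback)/dm = 2 G m, (2,2) = 0.
    """
    m, xi = state.m, state.xi
    J = np.array(
        [
            [drift_dm(m, xi, spec), -m],
            [2.0 * fb.G * m, 0.0],
        ]
    )
    return JacobianReport.from_matrix(J)


def eigenvalues(report: JacobianReport) -> tuple[complex, complex]:
    """Eigenvalues lambda = [T +- sqrt(T^2 - 4 Delta)]/2 of a 2x2 Jacobian."""
    return _eig_from_trace_det(report.trace, report.det)


def classify(report: JacobianReport, *, tol: float = SIGN_TOL) -> str:
    """Poincare-diagram label from (trace, det, discriminant) sign pattern.

    Boundary values (within ``tol`` of zero) return the degenerate label
    rather than an arbitrary side.
    """
    T, D = report.trace, report.det
    disc = T * T - 4.0 * D
    if D < -tol:
        return "saddle"
    if abs(D) <= tol:
        return "nonhyperbolic"
    # D > 0 from here on
    if abs(T) <= tol:
        return "center_candidate"
    if abs(disc) <= tol:
        return "stable_degenerate_node" if T < 0 else "unstable_node"
    if T < 0:
        return "stable_spiral" if disc < 0 else "stable_node"
    return "unstable_spiral" if disc < 0 else "unstable_node"


def admissible_M_range(spec: ModelSpec) -> float:
    """Upper bound on M keeping xi* >= 0 at every equilibrium branch.

    model1 -> 1, model2 -> sqrt((1+sqrt(5))/2) ~ 1.272,
    model3 -> (sqrt(5)-1)/2 ~ 0.618.
    """
    return admissible_upper_bound(spec)


@dataclass(frozen=True)
class HopfResult:
    exists: bool
    Mc: float | None = None
    branch: str | None = None  # "E_plus" | "E_minus"
    character: str = "undetermined"  # "supercritical" | "subcritical" | "undetermined"


def _trace_roots_on_branch(spec: ModelSpec, sgn: float, M_max: float) -> list[float]:
    """Positive roots of T(M) = -alpha m - 2 beta m^2 - 4 gamma m^4 at m = sgn*M."""
    # polynomial in M: -4 gamma M^4 - 2 beta M^2 - sgn*alpha M
    coeffs = np.array([-4.0 * spec.gamma, 0.0, -2.0 * spec.beta, -sgn * spec.alpha, 0.0])
    nz = np.nonzero(coeffs)[0]
    if len(nz) == 0:
        return []
    coeffs = coeffs[nz[0]:]
    if len(coeffs) < 2:
        return []
    dcoeffs = np.polyder(coeffs)
    out = []
    for r in np.roots(coeffs):
        if abs(r.imag) > 1e-10:
            continue
        M = float(r.real)
        if M < 1e-9 or M >= M_max - 1e-12:
            continue
        if abs(np.polyval(dcoeffs, M)) < 1e-12:
            continue  # no sign change: transversality fails
        out.append(M)
    return sorted(out)


def hopf_point(
    spec: ModelSpec,
    fb_G: float,
    *,
    assess_character: bool = True,
    offset: float = 0.02,
    t_final: float = 1200.0,
) -> HopfResult:
    """Locate the Hopf candidate Mc where T(J) = 0 with Delta(J) > 0.

    Scans both equilibrium branches for the smallest admissible positive root
    of the trace.  ``exists=False`` when neither branch has one (model 1,
    whose trace -2M^2 is strictly negative for M > 0).  With
    ``assess_character=True`` the sub/supercritical character is decided by
    deterministic simulation at Mc -+ ``offset``: a small stable orbit below
    Mc together with convergence above it signals a supercritical Hopf.
    """
    if fb_G <= 0:
        raise ValueError(f"Hopf analysis needs G > 0, got {fb_G}")
    M_max = admissible_upper_bound(spec)
    candidates: list[tuple[float, str]] = []
    for sgn, label in ((+1.0, "E_plus"), (-1.0, "E_minus")):
        for M in _trace_roots_on_branch(spec, sgn, M_max):
            # Delta = 2 G M^2 > 0 automatically for M > 0
            candidates.append((M, label))
    if not candidates:
        return HopfResult(exists=False)
    # smallest Mc; prefer the E_plus branch on symmetric ties
    Mc, branch = min(candidates, key=lambda c: (c[0], c[1] != "E_plus"))
    character = "undetermined"
    if assess_character:
        character = _assess_character(spec, fb_G, Mc, branch, offset, t_final)
    return HopfResult(exists=True, Mc=Mc, branch=branch, character=character)


def _assess_character(
    spec: ModelSpec, G: float, Mc: float, branch: str, offset: float, t_final: float
) -> str:
    """Simulate just below and above Mc from a small perturbation of E."""
    from .observables import limit_cycle_summary
    from .simulate import SimulationConfig, simulate

    sgn = 1.0 if branch == "E_plus" else -1.0
    results = {}
    for side, M in (("below", Mc - offset), ("above", Mc + offset)):
        if M <= 0 or xi_star(spec, sgn * M) < 0 or xi_star(spec, -sgn * M) < 0:
            return "undetermined"
        m_eq = sgn * M
        cfg = SimulationConfig(
            t_final=t_final,
            dt=1e-3,
            sigma=0.0,
            initial_state=SystemState(m_eq + 0.02, xi_star(spec, m_eq)),
        )
        traj = simulate(spec, FeedbackParams(G, M), cfg)
        results[side] = limit_cycle_summary(traj, transient_fraction=0.5)
    below, above = results["below"], results["above"]
    if below.is_cycle and not above.is_cycle:
        return "supercritical"
    if not below.is_cycle:
        return "subcritical"
    return "undetermined"
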