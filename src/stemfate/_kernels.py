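"""Numba-compiled inner loops.

The Euler-Maruyama recurrence and the fixed-noise gradient-flow relaxation are
strictly sequential in time, so they are written as scalar loops and jitted.
Everything array-shaped (noise draws, recording buffers) is allocated by the
callers with numpy.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def em_path(m0, xi0, alpha, beta, gamma, G, M, dt, nsteps, sigma, noise, stride, clamp_xi):
    """Integrate one trajectory of the coupled (m, xi) system.

    Returns (m_rec, xi_rec, abort_step); abort_step is -1 on success, else the
    index of the step at which the state became non-finite (the recorded
    arrays are then truncated to what was stored before the blow-up).
    """
    nrec = nsteps // stride + 1
    m_rec = np.empty(nrec)
    xi_rec = np.empty(nrec)
    m = m0
    xi = xi0
    m_rec[0] = m
    xi_rec[0] = xi
    sq = sigma * np.sqrt(dt)
    k = 0
    M2 = M * M
    for i in range(nsteps):
        f = (1.0 - xi) * m - alpha * m * m - beta * m**3 - gamma * m**5
        dxi = G * (m * m - M2) * dt
        if sigma > 0.0:
            m = m + f * dt + sq * noise[i]
        else:
            m = m + f * dt
        xi = xi + dxi
        if clamp_xi and xi < 0.0:
            xi = 0.0
        if not (np.isfinite(m) and np.isfinite(xi)):
            return m_rec[: k + 1], xi_rec[: k + 1], i
        if (i + 1) % stride == 0:
            k += 1
            m_rec[k] = m
            xi_rec[k] = xi
    return m_rec[: k + 1], xi_rec[: k + 1], -1


@njit(cache=False)
def relax_fixed_xi(m0, xi, alpha, beta, gamma, dt, tol, max_iter):
    """Damped gradient flow dm/dt = drift(m, xi) to steady state at fixed xi.

    Returns the settled m once |drift| < tol, NaN on blow-up, or the current
    iterate when max_iter is exhausted (slow convergence near degenerate
    roots; the residual is then still decreasing).
    """
    m = m0
    for _ in range(max_iter):
        f = (1.0 - xi) * m - alpha * m * m - beta * m**3 - gamma * m**5
        if abs(f) < tol:
            return m
        m = m + dt * f
        if not np.isfinite(m):
            return np.nan
    return m
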