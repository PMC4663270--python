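"""Compiled Dormand-Prince 5(4) integrator for the HR network.

The adaptive step-size controller, error norm and quartic dense-output
interpolant follow the standard explicit Runge-Kutta 4(5) formulation, so a
run is interchangeable (to tolerance) with ``scipy.integrate.solve_ivp``'s
RK45 — which the test suite uses as the independent oracle on short runs.
Everything here is nopython-compiled: at tolerance 1e-10 over 5e4 time units
the step count runs into the millions and per-step interpreter overhead
dominates otherwise.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Dormand-Prince tableau (same coefficients as scipy's RK45)
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0])
_A = np.zeros((6, 5))
_A[1, 0] = 1 / 5
_A[2, :2] = (3 / 40, 9 / 40)
_A[3, :3] = (44 / 45, -56 / 15, 32 / 9)
_A[4, :4] = (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729)
_A[5, :5] = (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656)
_B = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84])
_E = np.array(
    [71 / 57600, 0.0, -71 / 16695, 71 / 1920, -17253 / 339200, 22 / 525, -1 / 40]
)
# dense-output polynomial coefficients (7 stages x quartic in the step fraction)
_P = np.array(
    [
        [
            1.0,
            -8048581381 / 2820520608,
            8663915743 / 2820520608,
            -12715105075 / 11282082432,
        ],
        [0.0, 0.0, 0.0, 0.0],
        [
            0.0,
            131558114200 / 32700410799,
            -68118460800 / 10900136933,
            87487479700 / 32700410799,
        ],
        [
            0.0,
            -1754552775 / 470086768,
            14199869525 / 1410260304,
            -10690763975 / 1880347072,
        ],
        [
            0.0,
            127303824393 / 49829197408,
            -318862633887 / 49829197408,
            701980252875 / 199316789632,
        ],
        [
            0.0,
            -282668133 / 205662961,
            2019193451 / 616988883,
            -1453857185 / 822651844,
        ],
        [0.0, 40617522 / 29380423, -110615467 / 29380423, 69997945 / 29380423],
    ]
)

_SAFETY = 0.9
_MIN_FACTOR = 0.2
_MAX_FACTOR = 10.0


@njit(cache=True)
def _rhs(y, P, pre, post, kk, out):
    """HR network vector field; P rows are (a,b,c,d,s,r,x_st,J0,C)."""
    n = P.shape[0]
    for i in range(n):
        x = y[3 * i]
        out[3 * i] = P[i, 7]  # accumulate J0 + coupling into the x slot
    for e in range(pre.shape[0]):
        i, j = pre[e], post[e]
        out[3 * j] += kk[e] * (y[3 * i] - y[3 * j])
    for i in range(n):
        a, b, c, d, s, r, x_st, _, C = (
            P[i, 0], P[i, 1], P[i, 2], P[i, 3], P[i, 4],
            P[i, 5], P[i, 6], P[i, 7], P[i, 8],
        )
        x = y[3 * i]
        v = y[3 * i + 1]
        z = y[3 * i + 2]
        out[3 * i] = (v + x * x * (b - a * x) - z + out[3 * i]) / C
        out[3 * i + 1] = c - d * x * x - v
        out[3 * i + 2] = r * (s * (x - x_st) - z)


@njit(cache=True)
def _error_norm(K, h, y0, y1, rtol, atol, E):
    n = y0.shape[0]
    acc = 0.0
    for j in range(n):
        e = 0.0
        for s in range(7):
            e += E[s] * K[s, j]
        e *= h
        sc = atol + rtol * max(abs(y0[j]), abs(y1[j]))
        acc += (e / sc) * (e / sc)
    return np.sqrt(acc / n)


@njit(cache=True)
def _initial_step(P, pre, post, kk, y0, f0, rtol, atol):
    n = y0.shape[0]
    d0 = 0.0
    d1 = 0.0
    for j in range(n):
        sc = atol + rtol * abs(y0[j])
        d0 += (y0[j] / sc) ** 2
        d1 += (f0[j] / sc) ** 2
    d0 = np.sqrt(d0 / n)
    d1 = np.sqrt(d1 / n)
    h0 = 1e-6 if (d0 < 1e-5 or d1 < 1e-5) else 0.01 * d0 / d1
    y1 = y0 + h0 * f0
    f1 = np.empty(n)
    _rhs(y1, P, pre, post, kk, f1)
    d2 = 0.0
    for j in range(n):
        sc = atol + rtol * abs(y0[j])
        d2 += ((f1[j] - f0[j]) / sc) ** 2
    d2 = np.sqrt(d2 / n) / h0
    if d1 <= 1e-15 and d2 <= 1e-15:
        h1 = max(1e-6, h0 * 1e-3)
    else:
        h1 = (0.01 / max(d1, d2)) ** 0.2
    return min(100 * h0, h1)


@njit(cache=True)
def integrate_dopri5(P, pre, post, kk, y0, t_end, t_grid, rtol, atol):
    """Integrate from t=0 to t_end, sampling the dense output on t_grid.

    Returns (ys, t_fail, n_steps): ys has shape (len(t_grid), dim); t_fail is
    negative on success, else the time where the step size underflowed or the
    state left the finite range.
    """
    dim = y0.shape[0]
    ngrid = t_grid.shape[0]
    ys = np.empty((ngrid, dim))
    K = np.empty((7, dim))
    ytmp = np.empty(dim)
    f0 = np.empty(dim)
    _rhs(y0, P, pre, post, kk, f0)
    for j in range(dim):
        K[6, j] = f0[j]  # FSAL slot holds f(t, y)

    t = 0.0
    y = y0.copy()
    h = _initial_step(P, pre, post, kk, y0, f0, rtol, atol)
    ig = 0
    n_steps = 0
    while ig < ngrid and t_grid[ig] <= t:
        for j in range(dim):
            ys[ig, j] = y[j]
        ig += 1

    while t < t_end:
        if h < 1e-13 * max(1.0, abs(t)):
            return ys, t, n_steps
        if t + h > t_end:
            h = t_end - t
        # stages (first stage reuses last step's seventh stage: FSAL)
        for j in range(dim):
            K[0, j] = K[6, j]
        for s in range(1, 6):
            for j in range(dim):
                acc = 0.0
                for q in range(s):
                    acc += _A[s, q] * K[q, j]
                ytmp[j] = y[j] + h * acc
            _rhs(ytmp, P, pre, post, kk, K[s])
        ynew = np.empty(dim)
        for j in range(dim):
            acc = 0.0
            for s in range(6):
                acc += _B[s] * K[s, j]
            ynew[j] = y[j] + h * acc
        _rhs(ynew, P, pre, post, kk, K[6])
        ok = True
        for j in range(dim):
            if not np.isfinite(ynew[j]):
                ok = False
        if not ok:
            return ys, t, n_steps
        err = _error_norm(K, h, y, ynew, rtol, atol, _E)
        if err <= 1.0:
            # accepted: emit dense output for grid points inside (t, t+h]
            t_new = t + h
            while ig < ngrid and t_grid[ig] <= t_new:
                x = (t_grid[ig] - t) / h
                x2 = x * x
                for j in range(dim):
                    acc = 0.0
                    for s in range(7):
                        p = (
                            _P[s, 0] * x
                            + _P[s, 1] * x2
                            + _P[s, 2] * x2 * x
                            + _P[s, 3] * x2 * x2
                        )
                        acc += p * K[s, j]
                    ys[ig, j] = y[j] + h * acc
                ig += 1
            t = t_new
            for j in range(dim):
                y[j] = ynew[j]
            n_steps += 1
            factor = _MAX_FACTOR if err == 0.0 else min(
                _MAX_FACTOR, _SAFETY * err ** -0.2
            )
            h *= factor
        else:
            h *= max(_MIN_FACTOR, _SAFETY * err ** -0.2)

    return ys, -1.0, n_steps


@njit(cache=True)
def integrate_rk4_fixed(P, pre, post, kk, y0, t_end, t_grid, dt):
    """Classical fixed-step RK4 at step dt, sampled on t_grid (cross-check
    mode; grid times are matched to the nearest step)."""
    dim = y0.shape[0]
    ngrid = t_grid.shape[0]
    ys = np.empty((ngrid, dim))
    k1 = np.empty(dim)
    k2 = np.empty(dim)
    k3 = np.empty(dim)
    k4 = np.empty(dim)
    ytmp = np.empty(dim)
    y = y0.copy()
    t = 0.0
    ig = 0
    half = 0.5 * dt
    nsteps = int(np.ceil(t_end / dt))
    for step in range(nsteps + 1):
        while ig < ngrid and t_grid[ig] <= t + half:
            for j in range(dim):
                ys[ig, j] = y[j]
            ig += 1
        if ig >= ngrid and t >= t_end:
            break
        _rhs(y, P, pre, post, kk, k1)
        for j in range(dim):
            ytmp[j] = y[j] + half * k1[j]
        _rhs(ytmp, P, pre, post, kk, k2)
        for j in range(dim):
            ytmp[j] = y[j] + half * k2[j]
        _rhs(ytmp, P, pre, post, kk, k3)
        for j in range(dim):
            ytmp[j] = y[j] + dt * k3[j]
        _rhs(ytmp, P, pre, post, kk, k4)
        for j in range(dim):
            y[j] += dt * (k1[j] + 2 * k2[j] + 2 * k3[j] + k4[j]) / 6.0
        t += dt
        fin = True
        for j in range(dim):
            if not np.isfinite(y[j]):
                fin = False
        if not fin:
            return ys, t
    return ys, -1.0
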