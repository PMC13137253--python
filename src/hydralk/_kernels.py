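"""Inner Monte Carlo sweep kernel.

A numba-jitted Metropolis sweep over pre-generated random draws; the
pure-Python caller in :mod:`hydralk.toy_simulator` generates all random
numbers with the seeded numpy generator, so the sampling logic (and the
draw order) is identical whether or not numba is present.  Without
numba the module-level fallback in ``toy_simulator`` is used instead.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if len(args) == 1 and callable(args[0]):
            return args[0]
        return deco


@njit(cache=False)
def sweep_kernel(
    pos: np.ndarray,
    box: float,
    js: np.ndarray,
    disp: np.ndarray,
    us: np.ndarray,
    beta: float,
    eps_ss: float,
    sig2_ss: float,
    rc2_ss: float,
    u_rc_ss: float,
    solute: np.ndarray,
    eps_x: np.ndarray,
    sig2_x: np.ndarray,
    rc2_su: float,
    u_rc_su: np.ndarray,
    lam: float,
    alpha: float,
    n_exp: int,
    cap: float,
):
    """One sweep of single-particle Metropolis moves; mutates ``pos``.

    Returns ``(n_accepted, sum of accepted energy changes)``.
    """
    n = pos.shape[0]
    m = solute.shape[0]
    lamn = lam**n_exp
    a0 = alpha * (1.0 - lam) ** 2
    acc = 0
    du_accum = 0.0
    for k in range(n):
        j = js[k]
        ox, oy, oz = pos[j, 0], pos[j, 1], pos[j, 2]
        nx = (ox + disp[k, 0]) % box
        ny = (oy + disp[k, 1]) % box
        nz = (oz + disp[k, 2]) % box
        du = 0.0
        if eps_ss > 0.0 and n > 1:
            for i in range(n):
                if i == j:
                    continue
                for (px, py, pz, sgn) in ((nx, ny, nz, 1.0), (ox, oy, oz, -1.0)):
                    dx = px - pos[i, 0]
                    dy = py - pos[i, 1]
                    dz = pz - pos[i, 2]
                    dx -= box * math.floor(dx / box + 0.5)
                    dy -= box * math.floor(dy / box + 0.5)
                    dz -= box * math.floor(dz / box + 0.5)
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 < rc2_ss:
                        x6 = (sig2_ss / r2) ** 3
                        u = 4.0 * eps_ss * (x6 * x6 - x6)
                        if u > cap:
                            u = cap
                        du += sgn * (u - u_rc_ss)
        if lamn > 0.0 and m > 0:
            for i in range(m):
                for (px, py, pz, sgn) in ((nx, ny, nz, 1.0), (ox, oy, oz, -1.0)):
                    dx = px - solute[i, 0]
                    dy = py - solute[i, 1]
                    dz = pz - solute[i, 2]
                    dx -= box * math.floor(dx / box + 0.5)
                    dy -= box * math.floor(dy / box + 0.5)
                    dz -= box * math.floor(dz / box + 0.5)
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 < rc2_su:
                        a = a0 + (r2 / sig2_x[i]) ** 3
                        inv = 1.0 / a
                        u = lamn * 4.0 * eps_x[i] * (inv * inv - inv)
                        if u > cap:
                            u = cap
                        du += sgn * (u - u_rc_su[i])
        if du <= 0.0 or us[k] < math.exp(-beta * du if beta * du < 700.0 else -700.0):
            pos[j, 0] = nx
            pos[j, 1] = ny
            pos[j, 2] = nz
            acc += 1
            du_accum += du
    return acc, du_accum
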