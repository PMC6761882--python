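"""Independent reference computations for cross-checking the main code
paths.

These deliberately use different algorithms from the production code: the
2D rate coefficient is recomputed by finite-difference solution of the
radial diffusion equation with an absorbing boundary (no Bessel-integral
quadrature), and encounter counting is recomputed by a naive per-frame
O(N^2) pure-Python scan (no cell lists, no vectorised bookkeeping).
"""

from __future__ import annotations

import numpy as np
from scipy.constants import Avogadro as N_A
from scipy.integrate import solve_ivp

__all__ = ["rate_coefficient_pde", "brute_force_new_encounters"]


def rate_coefficient_pde(D: float, R: float, times, n_r: int = 2500,
                         outer_factor: float = 150.0,
                         molar: bool = True) -> np.ndarray:
    """2D diffusion-controlled rate coefficient from the absorbing flux.

    Solves c_t = D (c_rr + c_r / r) on r in [R, R_out] with c(R) = 0,
    c(R_out) = 1, c(r, 0) = 1 by the method of lines on a log-spaced radial
    grid, then evaluates k(t) = 2 pi R D dc/dr |_(r=R) with a second-order
    one-sided difference.  Returns k in m^2 mol^-1 s^-1 (``molar=True``,
    i.e. multiplied by Avogadro's number) on the requested time grid.

    The outer boundary must stay outside the diffusion layer:
    outer_factor * R >> sqrt(D t_max).
    """
    ts = np.asarray(times, dtype=float)
    if np.any(ts <= 0):
        raise ValueError("times must be > 0")
    r = np.geomspace(R, outer_factor * R, n_r)
    if np.sqrt(D * ts[-1]) > 0.3 * r[-1]:
        raise ValueError("outer boundary too close; increase outer_factor")
    c0 = np.ones(n_r)
    c0[0] = 0.0
    rm, r0, rp = r[:-2], r[1:-1], r[2:]
    hm, hp = r0 - rm, rp - r0

    def rhs(t, c):
        dc = np.zeros_like(c)
        d2 = 2.0 * (c[:-2] / (hm * (hm + hp)) - c[1:-1] / (hm * hp)
                    + c[2:] / (hp * (hm + hp)))
        d1 = (c[2:] - c[:-2]) / (hm + hp)
        dc[1:-1] = D * (d2 + d1 / r0)
        return dc

    sol = solve_ivp(rhs, (ts[0] * 1e-6, ts[-1]), c0, t_eval=ts,
                    method="LSODA", rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"PDE integration failed: {sol.message}")
    h1, h2 = r[1] - r[0], r[2] - r[0]
    out = np.empty(ts.size)
    for i in range(ts.size):
        c = sol.y[:, i]
        dcdr = (-(h2**2 - h1**2) * c[0] + h2**2 * c[1] - h1**2 * c[2]) \
            / (h1 * h2 * (h2 - h1))
        out[i] = 2.0 * np.pi * R * D * dcdr
    return out * N_A if molar else out


def brute_force_new_encounters(traj, radius: float) -> np.ndarray:
    """Mean cumulative new-encounter count by a naive per-frame O(N^2)
    pure-Python scan (reference for the production counter).  Matches the
    production convention: neighbours at t0 are excluded, each partner
    counted at most once per focal particle."""
    L = traj.box
    pos = traj.positions
    if not traj.wrapped:
        pos = np.mod(pos, np.asarray(L))
    N, F = traj.n_particles, traj.n_frames
    r2 = radius * radius

    def close(f, i, j):
        dx = pos[i, f, 0] - pos[j, f, 0]
        dy = pos[i, f, 1] - pos[j, f, 1]
        dx -= L[0] * round(dx / L[0])
        dy -= L[1] * round(dy / L[1])
        return dx * dx + dy * dy < r2

    known = [set() for _ in range(N)]
    for i in range(N):
        for j in range(N):
            if i != j and close(0, i, j):
                known[i].add(j)
    baseline = [len(s) for s in known]
    counts = np.zeros(F)
    for f in range(1, F):
        for i in range(N):
            for j in range(N):
                if i != j and j not in known[i] and close(f, i, j):
                    known[i].add(j)
        counts[f] = np.mean([len(known[i]) - baseline[i] for i in range(N)])
    return counts
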