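"""Independent numerical oracles the model implementations are checked against.

These deliberately avoid the package's convolution/grid code paths:
the 2TCM oracle integrates the compartment ODE system with
``scipy.integrate.solve_ivp``; the reference-tissue oracle evaluates the
convolution integral by direct trapezoid quadrature on a fine grid; the
NNLS oracle scans a dense grid over the weight simplex.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from pkquant.core import FrameSchedule


def ode_2tcm_frame_averages(params, blood, schedule: FrameSchedule,
                            rtol=1e-9, atol=1e-12) -> np.ndarray:
    """Frame-averaged 2TCM output by ODE integration of the compartments."""
    shifted = blood.with_delay(blood.delay + params.delay)

    def cp(t):
        return shifted.interp(np.atleast_1d(max(t, 0.0)), "plasma",
                              warn_extrapolate=False)[0]

    def rhs(t, y):
        c1, c2 = y
        return [params.K1 * cp(t) - (params.k2 + params.k3) * c1 + params.k4 * c2,
                params.k3 * c1 - params.k4 * c2]

    sol = solve_ivp(rhs, [0.0, schedule.scan_end], [0.0, 0.0], rtol=rtol,
                    atol=atol, dense_output=True, max_step=0.25)
    out = np.empty(schedule.n_frames)
    for j, (a, b) in enumerate(zip(schedule.start_times, schedule.end_times)):
        tt = np.linspace(a, b, 61)
        ct = sol.sol(tt).sum(axis=0)
        wb = shifted.interp(tt, "whole_blood", warn_extrapolate=False)
        y = (1.0 - params.vB) * ct + params.vB * wb
        out[j] = np.trapezoid(y, tt) / (b - a)
    return out


def srtm_midpoint_values_quadrature(params, ref, n_grid=60001) -> np.ndarray:
    """SRTM operational equation with the convolution done by direct
    trapezoid quadrature of C_R(s) e^{-k2a (t - s)} on a fine grid."""
    sched = ref.schedule
    mids = sched.midpoints
    t = np.linspace(0.0, sched.scan_end, n_grid)
    cr = np.interp(t, np.concatenate(([0.0], mids)),
                   np.concatenate(([0.0], ref.values)))
    k2a = params.k2 / (1.0 + params.bp)
    conv = np.empty(mids.size)
    for j, tm in enumerate(mids):
        sel = t <= tm
        conv[j] = np.trapezoid(cr[sel] * np.exp(-k2a * (tm - t[sel])), t[sel])
    return params.R1 * ref.values + (params.k2 - params.R1 * k2a) * conv


from functools import lru_cache


@lru_cache(maxsize=4)
def _simplex_grid(k: int, n_ticks: int) -> np.ndarray:
    def combos(remaining, slots):
        if slots == 1:
            yield (remaining,)
            return
        for v in range(remaining + 1):
            for rest in combos(remaining - v, slots - 1):
                yield (v,) + rest

    return np.array(list(combos(n_ticks, k)), dtype=float) / n_ticks


def simplex_grid_nnls(A: np.ndarray, b: np.ndarray, step=0.01) -> np.ndarray:
    """Brute-force counterpart of rescaled non-negative least squares.

    Any nonnegative weight vector factors as scale * (unit-sum direction),
    so the quadrant problem min_{w >= 0} ||A w - b|| is scanned as a dense
    grid over the direction simplex with the optimal scale per direction
    in closed form. Returns the best unit-sum direction.
    """
    grid = _simplex_grid(A.shape[1], int(round(1 / step)))
    M = A @ grid.T  # frames x gridpoints
    mb = b @ M
    mm = np.einsum("ij,ij->j", M, M)
    s = np.clip(mb / mm, 0.0, None)
    cost = np.einsum("i,i->", b, b) - 2 * s * mb + s * s * mm
    return grid[np.argmin(cost)]


def scaled_cost(A: np.ndarray, b: np.ndarray, direction: np.ndarray) -> float:
    """Cost ||A (s* direction) - b||^2 at the optimal nonnegative scale."""
    m = A @ direction
    s = max(float(m @ b) / float(m @ m), 0.0)
    r = s * m - b
    return float(r @ r)


def nearest_grid_direction(direction: np.ndarray, step=0.01) -> np.ndarray:
    """Round a unit-sum direction onto the simplex grid."""
    ticks = np.round(np.asarray(direction) / step).astype(int)
    # restore the unit sum on the largest coordinate
    ticks[np.argmax(ticks)] += int(round(1 / step)) - ticks.sum()
    return np.clip(ticks, 0, None) / (ticks.sum() if ticks.sum() else 1)
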