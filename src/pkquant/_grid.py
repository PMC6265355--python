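"""Dense-grid numerics shared by the compartment models.

The forward models are evaluated on a uniform fine time grid (default 1-s
spacing). Convolution of a piecewise-linear input with a decaying
exponential is computed exactly per grid interval via the recurrence

    y[n+1] = y[n] * exp(-a*dt) + closed-form integral over the interval,

implemented as an order-1 IIR filter so the whole curve costs O(n) in C.
Frame averages are trapezoid integrals over each frame's grid span, with
linear interpolation at frame boundaries that fall between grid nodes.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from .core import FrameSchedule

#: default grid spacing, minutes (1 second)
DT = 1.0 / 60.0


def dense_grid(schedule: FrameSchedule, dt: float = DT) -> np.ndarray:
    """Uniform grid from 0 to the scan end, inclusive of both ends."""
    n = int(round(schedule.scan_end / dt))
    return np.linspace(0.0, n * dt, n + 1)


def exp_conv(a: float, t: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Exact convolution (e^{-a s} * f)(t) for piecewise-linear f on uniform t."""
    dt = t[1] - t[0]
    x = a * dt
    e = np.exp(-x)
    if x > 1e-5:
        i0 = (1.0 - e) / a                    # int_0^dt e^{-a s} ds
        i1 = (1.0 - e * (1.0 + x)) / (a * a)  # int_0^dt s e^{-a s} ds
    else:  # series expansion keeps a -> 0 well-conditioned
        i0 = dt * (1.0 - x / 2.0 + x * x / 6.0)
        i1 = dt * dt * (0.5 - x / 3.0 + x * x / 8.0)
    fa, fb = f[:-1], f[1:]
    # contribution of one interval, integrating back from its right edge
    c = fb * i0 + (fa - fb) * i1 / dt
    y = lfilter([1.0], [1.0, -e], c)
    return np.concatenate(([0.0], y))


def frame_average(t: np.ndarray, y: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
    """Time-average of a gridded curve over each frame (trapezoid rule)."""
    out = np.empty(schedule.n_frames)
    for j, (a, b) in enumerate(zip(schedule.start_times, schedule.end_times)):
        # interior nodes strictly inside (a, b) plus interpolated endpoints
        sel = (t > a) & (t < b)
        tt = np.concatenate(([a], t[sel], [b]))
        yy = np.concatenate(([np.interp(a, t, y)], y[sel], [np.interp(b, t, y)]))
        out[j] = np.trapezoid(yy, tt) / (b - a)
    return out
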