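"""Weighted nonlinear least squares with deterministic multistart.

Starts are drawn log-uniformly within the bounds for parameters whose lower
bound is positive (rate constants) and uniformly otherwise (vB, delay, bp).
All draws come from a caller-supplied seed, so fits are reproducible. The
full set of starts is screened on raw cost and only the best few are
polished with :func:`scipy.optimize.least_squares`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


class FitError(RuntimeError):
    """No multistart converged, or the input is unusable for fitting."""


@dataclass
class FitResult:
    """Outcome of a weighted NLS fit."""

    params: object
    cost: float
    n_starts_converged: int
    best_start_index: int
    residuals: np.ndarray
    flags: list[str] = field(default_factory=list)

    def has_flag(self, name: str) -> bool:
        return name in self.flags


def draw_starts(bounds: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = bounds[:, 0], bounds[:, 1]
    u = rng.random((n, lo.size))
    log_ok = lo > 0
    starts = np.where(
        log_ok,
        np.exp(np.log(np.where(log_ok, lo, 1.0)) +
               u * (np.log(np.where(log_ok, hi, 1.0)) - np.log(np.where(log_ok, lo, 1.0)))),
        lo + u * (hi - lo),
    )
    return starts


def multistart_lsq(
    residual_fn,
    bounds: np.ndarray,
    *,
    n_starts: int = 100,
    n_refine: int = 5,
    seed: int = 0,
    x0_extra: np.ndarray | None = None,
) -> tuple[np.ndarray, float, int, int]:
    """Minimise sum(residual_fn(x)^2) over box bounds.

    Returns (x_best, cost, n_converged, best_start_index). ``x0_extra``
    rows are prepended to the random starts (e.g. a physiologic default).
    """
    bounds = np.asarray(bounds, dtype=float)
    rng = np.random.default_rng(seed)
    starts = draw_starts(bounds, n_starts, rng)
    if x0_extra is not None:
        starts = np.vstack([np.atleast_2d(x0_extra), starts])

    def cost_of(x):
        r = residual_fn(x)
        return float(np.dot(r, r))

    screen = np.array([cost_of(x) for x in starts])
    order = np.argsort(screen)[: max(1, n_refine)]
    best_x, best_cost, best_idx, n_conv = None, np.inf, -1, 0
    for idx in order:
        try:
            sol = least_squares(
                residual_fn, starts[idx], bounds=(bounds[:, 0], bounds[:, 1]),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
            )
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        n_conv += 1
        c = 2.0 * sol.cost  # scipy reports 0.5 * sum(r^2)
        if c < best_cost:
            best_x, best_cost, best_idx = sol.x, c, int(idx)
    if best_x is None:
        raise FitError("no multistart converged")
    return best_x, best_cost, n_conv, best_idx


def bound_hit_flags(x: np.ndarray, bounds: np.ndarray, names) -> list[str]:
    flags = []
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    at = (x - lo < 1e-6 * span) | (hi - x < 1e-6 * span)
    if np.any(at):
        hit = ",".join(n for n, a in zip(names, at) if a)
        flags.append(f"bound-hit:{hit}")
    return flags
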