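"""Two-tissue compartment model (2TCM) with arterial input.

The tissue impulse response is the standard bi-exponential

    h(t) = K1/(a2 - a1) * [(k3 + k4 - a1) e^{-a1 t} + (a2 - k3 - k4) e^{-a2 t}]
    a1,2 = ((k2 + k3 + k4) -/+ sqrt((k2 + k3 + k4)^2 - 4 k2 k4)) / 2

convolved with the delay-shifted metabolite-corrected plasma curve; the
measured frame value is the time-average over the frame of
``(1 - vB) * C_tissue + vB * C_whole_blood``.

The study-level procedure fits vB and the blood delay once on the whole
grey-matter TAC and holds both fixed for every other region (mode
``gm_anchored``); the sensitivity variant refits vB per region with the
delay still anchored to grey matter (mode ``per_roi_vB``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fitting import FitError, FitResult, bound_hit_flags, multistart_lsq
from ._grid import DT, dense_grid, exp_conv, frame_average
from .core import TAC, BloodInput, FrameSchedule

__all__ = ["TwoTCMParams", "simulate_2tcm", "fit_2tcm", "fit_study_2tcm",
           "DEFAULT_BOUNDS_2TCM"]


@dataclass(frozen=True)
class TwoTCMParams:
    """Rate constants of the 2TCM plus blood volume fraction and delay.

    K1 in mL·cm^-3·min^-1; k2..k4 in 1/min; vB a fraction; delay in
    minutes (positive = blood later than tissue).
    """

    K1: float
    k2: float
    k3: float = 0.0
    k4: float = 0.0
    vB: float = 0.05
    delay: float = 0.0

    def __post_init__(self):
        if self.K1 < 0 or self.k2 < 0 or self.k3 < 0 or self.k4 < 0:
            raise ValueError("rate constants must be nonnegative")
        if self.k3 > 0 and self.k4 <= 0:
            raise ValueError("k3 > 0 requires k4 > 0 (reversible binding)")
        if not 0 <= self.vB < 1:
            raise ValueError("vB must lie in [0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.k3, self.k4, self.vB, self.delay])


# physiologic box constraints; the delay window is +/- 1 min
DEFAULT_BOUNDS_2TCM = {
    "K1": (1e-4, 2.0), "k2": (1e-4, 2.0), "k3": (1e-4, 2.0), "k4": (1e-4, 2.0),
    "vB": (0.0, 0.2), "delay": (-1.0, 1.0),
}


def _impulse_coefficients(K1, k2, k3, k4):
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    if disc < 0:  # impossible for nonnegative rates, barring rounding
        disc = 0.0
    root = np.sqrt(disc)
    if root < 1e-9 * max(s, 1.0):  # repeated root: nudge off the degeneracy
        k4 = k4 * (1.0 + 1e-9) + 1e-12
        s = k2 + k3 + k4
        root = np.sqrt(max(s * s - 4.0 * k2 * k4, 1e-24))
    a1 = 0.5 * (s - root)
    a2 = 0.5 * (s + root)
    c1 = K1 * (k3 + k4 - a1) / (a2 - a1)
    c2 = K1 * (a2 - k3 - k4) / (a2 - a1)
    return a1, a2, c1, c2


def tissue_curve_2tcm(params: TwoTCMParams, blood: BloodInput,
                      t: np.ndarray) -> np.ndarray:
    """Tissue concentration (no blood-volume term) on a uniform grid."""
    shifted = blood.with_delay(blood.delay + params.delay)
    cp = shifted.interp(t, "plasma", warn_extrapolate=False)
    if params.K1 == 0:
        return np.zeros_like(t)
    a1, a2, c1, c2 = _impulse_coefficients(params.K1, params.k2, params.k3, params.k4)
    return c1 * exp_conv(a1, t, cp) + c2 * exp_conv(a2, t, cp)


def simulate_2tcm(params: TwoTCMParams, blood: BloodInput,
                  schedule: FrameSchedule, dt: float = DT) -> TAC:
    """Frame-averaged model TAC including the vascular contribution."""
    t = dense_grid(schedule, dt)
    ct = tissue_curve_2tcm(params, blood, t)
    shifted = blood.with_delay(blood.delay + params.delay)
    wb = shifted.interp(t, "whole_blood", warn_extrapolate=False)
    curve = (1.0 - params.vB) * ct + params.vB * wb
    return TAC(schedule, frame_average(t, curve, schedule), region_label="2tcm-model")


def _bounds_array(names, bounds):
    merged = dict(DEFAULT_BOUNDS_2TCM)
    if bounds:
        merged.update(bounds)
    return np.array([merged[n] for n in names], dtype=float)


def fit_2tcm(
    tac: TAC,
    blood: BloodInput,
    *,
    fit_vB: bool = True,
    fit_delay: bool = True,
    fixed_vB: float = 0.05,
    fixed_delay: float = 0.0,
    bounds: dict | None = None,
    n_starts: int = 100,
    n_refine: int = 5,
    weights: np.ndarray | None = None,
    seed: int = 0,
    dt: float = DT,
) -> FitResult:
    """Weighted multistart NLS fit of the 2TCM to one regional TAC."""
    obs = tac.values
    if not np.any(obs != 0):
        raise FitError("all-zero TAC: nothing to fit")
    w = tac.effective_weights() if weights is None else np.asarray(weights, float)
    sw = np.sqrt(w)
    n_free = 4 + int(fit_vB) + int(fit_delay)
    if np.count_nonzero(w) < n_free + 2:
        raise FitError("need at least 6 usable frames more than free parameters")

    names = ["K1", "k2", "k3", "k4"] + (["vB"] if fit_vB else []) + \
        (["delay"] if fit_delay else [])
    barr = _bounds_array(names, bounds)
    t = dense_grid(tac.schedule, dt)
    schedule = tac.schedule

    def unpack(x):
        vB = x[4] if fit_vB else fixed_vB
        delay = x[4 + int(fit_vB)] if fit_delay else fixed_delay
        return TwoTCMParams(x[0], x[1], x[2], x[3], vB, delay)

    def model_values(p: TwoTCMParams):
        ct = tissue_curve_2tcm(p, blood, t)
        wb = blood.with_delay(blood.delay + p.delay).interp(
            t, "whole_blood", warn_extrapolate=False)
        return frame_average(t, (1 - p.vB) * ct + p.vB * wb, schedule)

    def residuals(x):
        return sw * (obs - model_values(unpack(x)))

    x0 = np.array([0.1, 0.3, 0.05, 0.05] + ([0.05] if fit_vB else []) +
                  ([0.0] if fit_delay else []))
    x, cost, n_conv, idx = multistart_lsq(
        residuals, barr, n_starts=n_starts, n_refine=n_refine, seed=seed,
        x0_extra=x0)
    params = unpack(x)
    flags = bound_hit_flags(x, barr, names)
    if tac.is_short_scan:
        flags.append("short-scan")
    return FitResult(params, cost, n_conv, idx, residuals(x) / sw, flags)


def fit_study_2tcm(
    region_tacs: dict[str, TAC],
    blood: BloodInput,
    mode: str = "gm_anchored",
    gm_label: str = "GM",
    **fit_kw,
) -> dict[str, FitResult]:
    """Apply the 2TCM to every region with the study's anchoring scheme.

    ``gm_anchored``: vB and delay are estimated once on the whole-GM TAC
    (all six parameters free) and held fixed for every region.
    ``per_roi_vB``: the delay is still taken from the GM fit, but vB is
    re-estimated for each region.
    """
    if mode not in ("gm_anchored", "per_roi_vB"):
        raise ValueError(f"unknown mode {mode!r}")
    if gm_label not in region_tacs:
        raise ValueError(
            f"mode {mode!r} needs a whole-GM region labelled {gm_label!r}")
    gm_fit = fit_2tcm(region_tacs[gm_label], blood, fit_vB=True, fit_delay=True,
                      **fit_kw)
    vB_gm, delay_gm = gm_fit.params.vB, gm_fit.params.delay
    results = {gm_label: gm_fit}
    for region, tac in region_tacs.items():
        if region == gm_label:
            continue
        if mode == "gm_anchored":
            results[region] = fit_2tcm(
                tac, blood, fit_vB=False, fit_delay=False,
                fixed_vB=vB_gm, fixed_delay=delay_gm, **fit_kw)
        else:
            results[region] = fit_2tcm(
                tac, blood, fit_vB=True, fit_delay=False,
                fixed_delay=delay_gm, **fit_kw)
    return results
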