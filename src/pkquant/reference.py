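"""Reference-tissue quantification: SRTM, vascular-corrected SRTMv, IDIF.

SRTM operational equation, with ``k2a = k2 / (1 + bp)``:

    C_T(t) = R1 * C_R(t) + (k2 - R1 * k2a) * (C_R * e^{-k2a t})(t)

The reference curve is known only at frame midpoints, so the model is
evaluated at frame midpoints (with the convolution computed exactly on a
dense grid from the piecewise-linear reference curve). When the reference
region carries specific binding — cerebellum or an SVCA4-derived curve for
a TSPO ligand — the fitted ``bp`` is a *pseudo* binding potential.

SRTMv adds fractional blood volume in both target and reference, using an
image-derived blood curve C_b:

    C_obs,T = (1 - vB_t) * SRTM(R1, k2, bp; C_ref,corr) + vB_t * C_b
    C_ref,corr = (C_obs,R - vB_r * C_b) / (1 - vB_r)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._fitting import FitError, FitResult, bound_hit_flags, multistart_lsq
from ._grid import dense_grid, exp_conv
from .core import TAC, FrameSchedule, VoxelDataset

#: grid step for reference-model convolutions, minutes. 1/96 min divides
#: the frame midpoints of quarter-minute schedules, so the piecewise-linear
#: reference curve has all its kinks on grid nodes and the convolution is
#: exact for it.
DT = 1.0 / 96.0

__all__ = ["SRTMParams", "SRTMvParams", "simulate_srtm", "fit_srtm",
           "fit_srtmv", "extract_idif"]


@dataclass(frozen=True)
class SRTMParams:
    """R1 (relative delivery), k2 (1/min) and bp (BP_ND or pseudo-BP_ND)."""

    R1: float
    k2: float
    bp: float

    def __post_init__(self):
        if self.R1 <= 0 or self.k2 <= 0:
            raise ValueError("R1 and k2 must be positive")
        if self.bp <= -1:
            raise ValueError("bp must exceed -1")

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.bp)


@dataclass(frozen=True)
class SRTMvParams(SRTMParams):
    """SRTM parameters plus blood-volume fractions in target and reference."""

    vB_t: float = 0.0
    vB_r: float = 0.0

    def __post_init__(self):
        super().__post_init__()
        for name in ("vB_t", "vB_r"):
            v = getattr(self, name)
            if not 0 <= v <= 0.2:
                raise ValueError(f"{name} must lie in [0, 0.2]")


DEFAULT_BOUNDS_SRTM = {
    "R1": (1e-2, 10.0), "k2": (1e-4, 2.0), "bp": (-0.99, 10.0),
    "vB_t": (0.0, 0.2), "vB_r": (0.0, 0.2),
}


def _continuous_from_frames(t: np.ndarray, schedule: FrameSchedule,
                            values: np.ndarray) -> np.ndarray:
    """Piecewise-linear curve through (0, 0) and the frame midpoints."""
    mids = np.concatenate(([0.0], schedule.midpoints))
    vals = np.concatenate(([0.0], values))
    return np.interp(t, mids, vals)


def _srtm_midpoint_values(params: SRTMParams, ref: TAC, dt: float = DT) -> np.ndarray:
    t = dense_grid(ref.schedule, dt)
    cr = _continuous_from_frames(t, ref.schedule, ref.values)
    conv = np.interp(ref.schedule.midpoints, t, exp_conv(params.k2a, t, cr))
    return params.R1 * ref.values + (params.k2 - params.R1 * params.k2a) * conv


def simulate_srtm(params: SRTMParams, ref: TAC, dt: float = DT) -> TAC:
    """Model target TAC at the reference TAC's frame midpoints."""
    return TAC(ref.schedule, _srtm_midpoint_values(params, ref, dt),
               region_label="srtm-model")


def fit_srtm(
    target: TAC,
    ref: TAC,
    *,
    bounds: dict | None = None,
    n_starts: int = 100,
    n_refine: int = 5,
    weights: np.ndarray | None = None,
    seed: int = 0,
    dt: float = DT,
) -> FitResult:
    """Weighted multistart NLS fit of SRTM; bp may legitimately be negative."""
    if target.schedule != ref.schedule:
        raise ValueError("target and reference must share a frame schedule")
    if not np.any(ref.values != 0):
        raise FitError("all-zero reference TAC")
    obs = target.values
    w = target.effective_weights() if weights is None else np.asarray(weights, float)
    sw = np.sqrt(w)
    names = ["R1", "k2", "bp"]
    merged = dict(DEFAULT_BOUNDS_SRTM)
    if bounds:
        merged.update(bounds)
    barr = np.array([merged[n] for n in names], dtype=float)

    t = dense_grid(ref.schedule, dt)
    cr = _continuous_from_frames(t, ref.schedule, ref.values)
    mids = ref.schedule.midpoints

    def model_values(x):
        r1, k2, bp = x
        k2a = k2 / (1.0 + bp)
        conv = np.interp(mids, t, exp_conv(k2a, t, cr))
        return r1 * ref.values + (k2 - r1 * k2a) * conv

    def residuals(x):
        return sw * (obs - model_values(x))

    x0 = np.array([1.0, 0.3, 0.5])
    x, cost, n_conv, idx = multistart_lsq(
        residuals, barr, n_starts=n_starts, n_refine=n_refine, seed=seed,
        x0_extra=x0)
    params = SRTMParams(*x)
    flags = bound_hit_flags(x, barr, names)
    # with bp ~ 0 and R1 ~ 1 the convolution coefficient vanishes and k2
    # no longer influences the model
    if abs(params.k2 - params.R1 * params.k2a) < 1e-4 * params.k2:
        flags.append("k2-weakly-identified")
    if target.is_short_scan:
        flags.append("short-scan")
    return FitResult(params, cost, n_conv, idx, residuals(x) / sw, flags)


def fit_srtmv(
    target: TAC,
    ref: TAC,
    blood_image: TAC,
    *,
    fit_vB_r: bool = True,
    bounds: dict | None = None,
    n_starts: int = 100,
    n_refine: int = 5,
    weights: np.ndarray | None = None,
    seed: int = 0,
    dt: float = DT,
) -> FitResult:
    """SRTM with blood-volume correction in target and reference TACs."""
    if target.schedule != ref.schedule or blood_image.schedule != ref.schedule:
        raise ValueError("target, reference and blood image must share a schedule")
    if not np.any(blood_image.values != 0):
        # without a blood curve the vB terms only rescale the reference, a
        # non-identifiable family; fall back to plain SRTM
        warnings.warn("all-zero blood curve: SRTMv reduces to SRTM", stacklevel=2)
        base = fit_srtm(target, ref, bounds=bounds, n_starts=n_starts,
                        n_refine=n_refine, weights=weights, seed=seed, dt=dt)
        params = SRTMvParams(base.params.R1, base.params.k2, base.params.bp,
                             0.0, 0.0)
        return FitResult(params, base.cost, base.n_starts_converged,
                         base.best_start_index, base.residuals,
                         base.flags + ["zero-blood-curve"])
    obs = target.values
    w = target.effective_weights() if weights is None else np.asarray(weights, float)
    sw = np.sqrt(w)
    names = ["R1", "k2", "bp", "vB_t"] + (["vB_r"] if fit_vB_r else [])
    merged = dict(DEFAULT_BOUNDS_SRTM)
    if bounds:
        merged.update(bounds)
    barr = np.array([merged[n] for n in names], dtype=float)

    t = dense_grid(ref.schedule, dt)
    mids = ref.schedule.midpoints
    cb = blood_image.values

    def model_values(x):
        r1, k2, bp, vb_t = x[:4]
        vb_r = x[4] if fit_vB_r else 0.0
        ref_corr = (ref.values - vb_r * cb) / (1.0 - vb_r)
        cr = _continuous_from_frames(t, ref.schedule, ref_corr)
        k2a = k2 / (1.0 + bp)
        conv = np.interp(mids, t, exp_conv(k2a, t, cr))
        srtm = r1 * ref_corr + (k2 - r1 * k2a) * conv
        return (1.0 - vb_t) * srtm + vb_t * cb

    def residuals(x):
        return sw * (obs - model_values(x))

    x0 = np.array([1.0, 0.3, 0.5, 0.05] + ([0.05] if fit_vB_r else []))
    x, cost, n_conv, idx = multistart_lsq(
        residuals, barr, n_starts=n_starts, n_refine=n_refine, seed=seed,
        x0_extra=x0)
    params = SRTMvParams(x[0], x[1], x[2], x[3], x[4] if fit_vB_r else 0.0)
    flags = bound_hit_flags(x, barr, names)
    if fit_vB_r and params.vB_r >= merged["vB_r"][1] - 1e-6:
        flags.append("reference-nearly-all-blood")
    if target.is_short_scan:
        flags.append("short-scan")
    return FitResult(params, cost, n_conv, idx, residuals(x) / sw, flags)


def extract_idif(
    voxels: VoxelDataset,
    n_voxels: int = 10,
    return_info: bool = False,
):
    """Image-derived blood curve from the hottest first-minute voxels.

    Voxels inside the brain mask are ranked by their time-weighted mean
    activity over the frames intersecting [0, 1] min (fractional overlap
    weighting for a frame straddling t = 1); the full TACs of the top
    ``n_voxels`` are averaged. Ties at the selection boundary are broken
    by voxel index and flagged.
    """
    schedule = voxels.schedule
    if schedule.start_times[0] > 0 or schedule.end_times[-1] < 1.0:
        raise ValueError("schedule must cover the first minute of the scan")
    idx_masked = np.flatnonzero(voxels.brain_mask)
    if idx_masked.size < n_voxels:
        raise ValueError(
            f"only {idx_masked.size} voxels in mask; need {n_voxels}")
    overlap = np.clip(np.minimum(schedule.end_times, 1.0) -
                      np.maximum(schedule.start_times, 0.0), 0.0, None)
    score = voxels.voxel_tacs[idx_masked] @ overlap / overlap.sum()
    # stable sort on -score => ties resolved by ascending voxel index
    order = np.argsort(-score, kind="stable")
    chosen = idx_masked[order[:n_voxels]]
    flags = []
    if idx_masked.size > n_voxels and \
            score[order[n_voxels - 1]] <= score[order[n_voxels]] + 1e-12:
        flags.append("selection-ties")
    tac = TAC(schedule, voxels.voxel_tacs[chosen].mean(axis=0),
              region_label="idif")
    if return_info:
        return tac, {"voxel_indices": chosen, "flags": flags}
    return tac
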