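"""Supervised cluster analysis (SVCA) reference extraction.

Each voxel TAC is normalised to unit area and decomposed by non-negative
least squares onto a set of unit-area population kinetic class curves
(grey matter with high / low specific binding, white matter, blood, plus
soft tissue and bone in the 6-class variant). SVCA4 restricts the classes
to the four brain classes inside an MRI-defined brain mask. The reference
TAC is the weight-averaged raw TAC of voxels loading on the low-binding
grey-matter class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import nnls

from .core import TAC, FrameSchedule, VoxelDataset

__all__ = [
    "KineticClassSet", "SVCAOptions", "BRAIN_CLASSES",
    "smooth_voxels", "align_classes", "svca_weights",
    "extract_reference_svca4", "estimate_classes",
]

BRAIN_CLASSES = ("gm_high_binding", "gm_low_binding", "white_matter", "blood")
EXTRACEREBRAL_CLASSES = ("soft_tissue", "bone")


def _unit_area(curves: np.ndarray, durations: np.ndarray) -> np.ndarray:
    """Scale each row so that sum(value * frame duration) == 1."""
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    area = curves @ durations
    if np.any(area <= 0):
        raise ValueError("class curve with non-positive area")
    return curves / area[:, None]


@dataclass
class KineticClassSet:
    """Ordered, unit-area population kinetic class curves on a schedule."""

    class_names: list[str]
    curves: np.ndarray
    schedule: FrameSchedule
    has_background_frame: bool = False

    def __post_init__(self):
        self.class_names = list(self.class_names)
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if self.curves.shape != (len(self.class_names), self.schedule.n_frames):
            raise ValueError("curves must be classes x frames on the schedule")
        self.curves = _unit_area(self.curves, self.schedule.durations)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, names) -> "KineticClassSet":
        idx = [self.class_names.index(n) for n in names]
        return KineticClassSet([self.class_names[i] for i in idx],
                               self.curves[idx], self.schedule,
                               self.has_background_frame)


@dataclass
class SVCAOptions:
    """Tunables of the SVCA pipeline (defaults follow the study set-up)."""

    smoothing_fwhm_mm: float = 4.0
    weight_threshold: float = 0.0
    normalization: str = "unit_area"
    class_subset: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("FWHM must be nonnegative")
        if not 0 <= self.weight_threshold <= 1:
            raise ValueError("weight_threshold must lie in [0, 1]")


FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_voxels(voxels: VoxelDataset, fwhm_mm: float) -> VoxelDataset:
    """Per-frame 3D Gaussian smoothing of an image-backed voxel dataset."""
    if fwhm_mm == 0:
        return voxels
    if voxels.grid_shape is None:
        warnings.warn("no grid geometry: spatial smoothing skipped", stacklevel=2)
        return voxels
    sigma_vox = np.array([fwhm_mm * FWHM_TO_SIGMA / s for s in voxels.voxel_size_mm])
    if fwhm_mm < min(voxels.voxel_size_mm):
        warnings.warn("smoothing FWHM below voxel size", stacklevel=2)
    img = voxels.voxel_tacs.reshape(*voxels.grid_shape, -1)
    out = np.empty_like(img)
    for f in range(img.shape[-1]):
        out[..., f] = gaussian_filter(img[..., f], sigma=sigma_vox, mode="constant")
    return VoxelDataset(out.reshape(voxels.n_voxels, -1), voxels.schedule,
                        brain_mask=voxels.brain_mask,
                        voxel_size_mm=voxels.voxel_size_mm,
                        grid_shape=voxels.grid_shape)


def align_classes(classes: KineticClassSet, target_schedule: FrameSchedule,
                  drop_background: bool = False) -> KineticClassSet:
    """Resample class curves onto a target schedule.

    Population class sets sometimes start with a 30-s background frame that
    the acquisition at hand lacks; ``drop_background`` removes it before
    resampling. Resampling is linear in time at frame midpoints, followed
    by re-normalisation to unit area.
    """
    curves, schedule = classes.curves, classes.schedule
    if drop_background:
        if not classes.has_background_frame:
            raise ValueError("class set has no background frame to drop")
        curves = curves[:, 1:]
        schedule = FrameSchedule(schedule.start_times[1:] - schedule.start_times[1],
                                 schedule.end_times[1:] - schedule.start_times[1])
    if schedule == target_schedule:
        return KineticClassSet(classes.class_names, curves, target_schedule, False)
    src_mid, dst_mid = schedule.midpoints, target_schedule.midpoints
    if dst_mid[-1] > schedule.end_times[-1] + 1e-9 or dst_mid[0] < schedule.start_times[0] - 1e-9:
        raise ValueError("target schedule extends beyond class curve support")
    resampled = np.vstack([np.interp(dst_mid, src_mid, c) for c in curves])
    return KineticClassSet(classes.class_names, resampled, target_schedule, False)


def svca_weights(
    voxels: VoxelDataset,
    classes: KineticClassSet,
    options: SVCAOptions | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative class weights per voxel, rescaled to sum 1.

    Voxel TACs are unit-area normalised, so the decomposition is invariant
    to the voxel's overall amplitude. The least-squares objective weights
    frames by their duration. Returns ``(weights, flagged)`` where
    ``flagged`` marks voxels with non-positive total activity or an
    all-zero NNLS solution (their weight rows are zero).
    """
    if options is None:
        options = SVCAOptions()
    if classes.schedule != voxels.schedule:
        raise ValueError("class curves must be aligned to the voxel schedule")
    cls = classes
    if options.class_subset is not None:
        cls = classes.subset(options.class_subset)
    dur = voxels.schedule.durations
    sq = np.sqrt(dur)
    A = (cls.curves * sq).T  # frames x classes, duration-weighted
    n = voxels.n_voxels
    weights = np.zeros((n, cls.n_classes))
    flagged = np.zeros(n, dtype=bool)
    area = voxels.voxel_tacs @ dur
    for i in range(n):
        if area[i] <= 0:
            flagged[i] = True
            continue
        b = (voxels.voxel_tacs[i] / area[i]) * sq
        w, _ = nnls(A, b)
        s = w.sum()
        if s <= 0:
            flagged[i] = True
            continue
        weights[i] = w / s
    return weights, flagged


def extract_reference_svca4(
    voxels: VoxelDataset,
    classes: KineticClassSet,
    options: SVCAOptions | None = None,
    *,
    reference_class: str = "gm_low_binding",
    presmoothed: bool = False,
) -> TAC:
    """Low-binding grey-matter reference TAC via brain-masked SVCA.

    Smoothing (default FWHM 4 mm) is applied before the decomposition when
    the dataset is image-backed; the reference average always uses the
    voxels' original (unnormalised) TACs, weighted by their low-binding GM
    class weight. Classes are restricted to the four brain classes.
    """
    if options is None:
        options = SVCAOptions()
    cls = classes
    if set(BRAIN_CLASSES).issubset(cls.class_names) and cls.n_classes > len(BRAIN_CLASSES):
        cls = cls.subset(BRAIN_CLASSES)
    if reference_class not in cls.class_names:
        raise ValueError(f"class set lacks {reference_class!r}")
    work = voxels if presmoothed else smooth_voxels(voxels, options.smoothing_fwhm_mm)
    masked = np.flatnonzero(voxels.brain_mask)
    if masked.size == 0:
        raise ValueError("empty brain mask")
    sub = VoxelDataset(work.voxel_tacs[masked], voxels.schedule)
    weights, _ = svca_weights(sub, cls, options)
    w = weights[:, cls.class_names.index(reference_class)]
    if options.weight_threshold > 0:
        w = np.where(w >= options.weight_threshold, w, 0.0)
    if w.sum() <= 0:
        raise ValueError(
            "no voxels assigned to the low-binding reference class")
    ref = (w[:, None] * voxels.voxel_tacs[masked]).sum(axis=0) / w.sum()
    return TAC(voxels.schedule, ref, region_label="svca4_reference")


def estimate_classes(voxels: VoxelDataset, labels) -> KineticClassSet:
    """Build a class set as per-label means of unit-area voxel TACs."""
    labels = np.asarray(labels)
    if labels.shape != (voxels.n_voxels,):
        raise ValueError("one label per voxel required")
    names = sorted(set(labels.tolist()))
    dur = voxels.schedule.durations
    curves = []
    for name in names:
        sel = voxels.voxel_tacs[labels == name]
        if sel.shape[0] == 0:
            raise ValueError(f"no voxels labelled {name!r}")
        curves.append(_unit_area(sel, dur).mean(axis=0))
    return KineticClassSet(names, np.vstack(curves), voxels.schedule)
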