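"""Synthetic dynamic-PET generation: plasma input, cohorts, voxel images.

The generator emulates the study design the statistics are meant for: a
small cohort (default 6 subjects) scanned twice ~6 weeks apart for 63 min,
five target regions plus cerebellum, TSPO-like kinetics with low specific
binding everywhere (including the pseudo-reference regions), and voxel
populations mixing four brain kinetic classes.

Plasma input is a tri-exponential Feng-type curve

    Cp(t) = (A1 (t - t0) - A2 - A3) e^{l1 (t - t0)}
            + A2 e^{l2 (t - t0)} + A3 e^{l3 (t - t0)},   t >= t0, else 0

with l1 < l2 < l3 < 0. Subject parameters are log-normal around the
population means (positivity); the session effect multiplies K1 and k3
(flow and binding channels). Frame noise is zero-mean Gaussian with
variance proportional to value / (duration * e^{-lambda * midpoint}), the
standard count-statistics approximation for decay-corrected TACs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._grid import dense_grid, frame_average
from .core import C11_LAMBDA, TAC, BloodInput, FrameSchedule, VoxelDataset, default_schedule
from .svca import BRAIN_CLASSES, EXTRACEREBRAL_CLASSES, KineticClassSet
from .tcm import TwoTCMParams, simulate_2tcm

__all__ = [
    "InputModelParams", "PopulationModel", "NoiseModel", "SimulatedStudy",
    "gen_input", "gen_trt_study", "gen_voxel_dataset",
    "make_population_class_set", "DEFAULT_REGION_EFFECTS", "TARGET_REGIONS",
]

TARGET_REGIONS = ("FC", "GM", "HIP", "STR", "THAL")
CEREBELLUM = "CER"

#: multiplicative region effects on the population-mean rate constants;
#: tuned so regional V_T ~ 0.7, 2TCM BP_ND ~ 1.4-2.0 (TSPO-like, low binding)
DEFAULT_REGION_EFFECTS: dict[str, dict[str, float]] = {
    "FC": {"k3": 0.95},
    "GM": {},
    "HIP": {"K1": 0.95, "k3": 1.20},
    "STR": {"K1": 1.05, "k3": 0.90},
    "THAL": {"K1": 1.05, "k3": 1.10},
    CEREBELLUM: {"K1": 0.92, "k2": 1.05, "k3": 1.10},
}


@dataclass(frozen=True)
class InputModelParams:
    """Feng-type plasma model; amplitudes kBq/mL (A1 kBq/mL/min)."""

    A1: float = 300.0
    A2: float = 10.0
    A3: float = 8.0
    lambda1: float = -4.0
    lambda2: float = -0.5
    lambda3: float = -0.008
    t0: float = 0.5

    def __post_init__(self):
        if not self.lambda1 <= self.lambda2 <= self.lambda3 < 0 and \
                not (self.A1 == self.A2 == self.A3 == 0):
            raise ValueError("need lambda1 <= lambda2 <= lambda3 < 0")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tau = t - self.t0
        curve = np.where(
            tau > 0,
            (self.A1 * tau - self.A2 - self.A3) * np.exp(self.lambda1 * tau)
            + self.A2 * np.exp(self.lambda2 * tau)
            + self.A3 * np.exp(self.lambda3 * tau),
            0.0,
        )
        return curve

    def scaled(self, factor: float) -> "InputModelParams":
        return replace(self, A1=self.A1 * factor, A2=self.A2 * factor,
                       A3=self.A3 * factor)


def gen_input(params: InputModelParams, schedule: FrameSchedule,
              blood_to_plasma=1.0) -> BloodInput:
    """Sample the plasma model densely (1-s spacing to 5 min, then one
    point per frame boundary and midpoint) and derive whole blood via the
    blood-to-plasma profile (a constant or a callable of time)."""
    early = np.arange(0.0, min(5.0, schedule.scan_end), 1.0 / 60.0)
    late_frames = schedule.midpoints[schedule.midpoints > 5.0]
    late_bounds = schedule.end_times[schedule.end_times > 5.0]
    times = np.unique(np.concatenate([early, [5.0], late_frames, late_bounds]))
    plasma = params(times)
    if np.any(plasma < -1e-9):
        raise ValueError("input model parameters give a negative plasma curve")
    plasma = np.clip(plasma, 0.0, None)
    ratio = blood_to_plasma(times) if callable(blood_to_plasma) else blood_to_plasma
    return BloodInput(times, plasma, plasma * ratio)


@dataclass
class NoiseModel:
    """Gaussian frame noise: var_j = sc^2 * value_j / (dur_j * e^{-lambda * mid_j})."""

    sc: float = 0.05
    decay_lambda: float = C11_LAMBDA
    mode: str = "count_proportional"

    def __post_init__(self):
        if self.sc < 0:
            raise ValueError("noise scale must be nonnegative")

    def frame_sigma(self, values: np.ndarray, schedule: FrameSchedule) -> np.ndarray:
        if self.sc == 0:
            return np.zeros_like(np.asarray(values, float))
        decay = np.exp(-self.decay_lambda * schedule.midpoints)
        var = np.clip(np.asarray(values, float), 0.0, None) / (schedule.durations * decay)
        return self.sc * np.sqrt(var)

    def apply(self, values: np.ndarray, schedule: FrameSchedule,
              rng: np.random.Generator) -> np.ndarray:
        if self.sc == 0:
            return np.asarray(values, float).copy()
        return values + rng.normal(0.0, 1.0, len(values)) * \
            self.frame_sigma(values, schedule)


@dataclass
class PopulationModel:
    """Log-normal population of 2TCM parameters with a session effect.

    ``sigma_between`` is the between-subject log-SD (scalar, applied to
    each of K1..k4 and vB unless a dict narrows it); ``sigma_within`` is
    the session log-SD, applied multiplicatively to ``within_channels``
    (default: K1 and k3 — the delivery and binding channels).
    """

    means: dict[str, float] = field(default_factory=lambda: {
        "K1": 0.10, "k2": 0.375, "k3": 0.05, "k4": 0.03, "vB": 0.05})
    sigma_between: float | dict[str, float] = 0.20
    sigma_within: float = 0.13
    within_channels: tuple[str, ...] = ("K1", "k3")
    delay_sd: float = 0.1
    blood_amp_between: float = 0.15
    blood_amp_within: float = 0.10
    dose_mean_MBq: float = 302.0
    dose_sd_MBq: float = 33.0
    weight_mean_kg: float = 75.0
    weight_sd_kg: float = 8.0
    seed: int = 0

    def session_invariant(self) -> "PopulationModel":
        """Copy with every within-session variance channel switched off."""
        return replace(self, sigma_within=0.0, delay_sd=0.0,
                       blood_amp_within=0.0, dose_sd_MBq=0.0)

    def _sb(self, name: str) -> float:
        if isinstance(self.sigma_between, dict):
            return float(self.sigma_between.get(name, 0.0))
        return float(self.sigma_between)

    def draw_subject(self, rng: np.random.Generator) -> dict[str, float]:
        out = {}
        for name, mu in self.means.items():
            for _ in range(100):
                v = mu * np.exp(rng.normal(0.0, self._sb(name)))
                if v > 0:
                    break
            out[name] = v
        out["vB"] = float(np.clip(out.get("vB", 0.05), 0.0, 0.15))
        return out

    def session_factors(self, rng: np.random.Generator) -> dict[str, float]:
        return {ch: float(np.exp(rng.normal(0.0, self.sigma_within)))
                for ch in self.within_channels}

    def true_icc(self) -> float:
        """ICC implied by the generating log-scale variance components
        for outcomes driven by the within channels (e.g. V_T via K1)."""
        sb = self._sb("K1") ** 2
        sw = self.sigma_within ** 2
        return sb / (sb + sw) if sb + sw > 0 else np.nan


@dataclass
class SimulatedStudy:
    """Everything a downstream stage needs, with ground truth attached."""

    schedule: FrameSchedule
    tacs: dict  # (subject, session) -> {region: TAC}
    blood: dict  # (subject, session) -> BloodInput (unshifted; true delay in truth)
    truth: pd.DataFrame
    dosimetry: pd.DataFrame  # subject, session, injected_dose_MBq, body_weight_kg
    population: PopulationModel
    noise: NoiseModel
    seed: int

    def subjects(self) -> list[str]:
        return sorted({k[0] for k in self.tacs})


def _derive_truth_row(p: dict) -> dict:
    bp = p["k3"] / p["k4"]
    vnd = p["K1"] / p["k2"]
    return {"V_T": vnd * (1 + bp), "V_S": vnd * bp, "BP_ND": bp}


def gen_trt_study(
    pop: PopulationModel | None = None,
    n_subjects: int = 6,
    regions: dict[str, dict[str, float]] | None = None,
    schedule: FrameSchedule | None = None,
    noise: NoiseModel | None = None,
    input_params: InputModelParams | None = None,
    seed: int | None = None,
) -> SimulatedStudy:
    """Simulate a two-session test-retest cohort of regional TACs."""
    pop = pop or PopulationModel()
    if n_subjects < 2:
        raise ValueError("need at least two subjects")
    regions = DEFAULT_REGION_EFFECTS if regions is None else regions
    schedule = schedule or default_schedule()
    noise = noise or NoiseModel()
    input_params = input_params or InputModelParams()
    seed = pop.seed if seed is None else int(seed)
    root = np.random.SeedSequence(seed)
    tacs, blood, truth_rows, dosi_rows = {}, {}, [], []
    for s, subj_seq in enumerate(root.spawn(n_subjects)):
        subject = f"S{s + 1:02d}"
        rng = np.random.default_rng(subj_seq)
        base = pop.draw_subject(rng)
        amp_subj = float(np.exp(rng.normal(0.0, pop.blood_amp_between)))
        weight = float(np.clip(rng.normal(pop.weight_mean_kg, pop.weight_sd_kg),
                               50.0, 110.0))
        for session in (1, 2):
            factors = pop.session_factors(rng)
            amp_sess = amp_subj * float(np.exp(rng.normal(0.0, pop.blood_amp_within)))
            delay_true = float(np.clip(rng.normal(0.0, pop.delay_sd), -0.8, 0.8)) \
                if pop.delay_sd > 0 else 0.0
            dose = float(np.clip(rng.normal(pop.dose_mean_MBq, pop.dose_sd_MBq),
                                 150.0, 450.0))
            bl = gen_input(input_params.scaled(amp_sess), schedule)
            blood[(subject, session)] = bl
            tacs[(subject, session)] = {}
            dosi_rows.append({"subject_id": subject, "session": session,
                              "injected_dose_MBq": dose,
                              "body_weight_kg": weight})
            for region, effects in regions.items():
                p = dict(base)
                for name, mult in effects.items():
                    p[name] = p[name] * mult
                for name, mult in factors.items():
                    p[name] = p[name] * mult
                params = TwoTCMParams(p["K1"], p["k2"], p["k3"], p["k4"],
                                      p["vB"], delay_true)
                clean = simulate_2tcm(params, bl, schedule)
                values = noise.apply(clean.values, schedule, rng)
                tacs[(subject, session)][region] = TAC(
                    schedule, values, region_label=region)
                truth_rows.append({
                    "subject_id": subject, "session": session, "region": region,
                    **p, "delay": delay_true, **_derive_truth_row(p),
                })
    truth = pd.DataFrame(truth_rows)
    return SimulatedStudy(schedule, tacs, blood, truth,
                          pd.DataFrame(dosi_rows), pop, noise, seed)


# --- kinetic class curves and voxel populations ---------------------------

#: 2TCM parameters behind the synthetic brain class curves; tissue classes
#: carry a physiologic ~5% blood volume (the blood class is the whole-blood
#: curve itself)
CLASS_KINETICS = {
    "gm_high_binding": TwoTCMParams(0.105, 0.375, 0.080, 0.030, vB=0.05),
    "gm_low_binding": TwoTCMParams(0.100, 0.375, 0.040, 0.030, vB=0.05),
    "white_matter": TwoTCMParams(0.040, 0.250, 0.040, 0.030, vB=0.03),
    "soft_tissue": TwoTCMParams(0.020, 0.300, 0.010, 0.020, vB=0.02),
    "bone": TwoTCMParams(0.005, 0.200, 0.005, 0.020, vB=0.01),
}


def make_population_class_set(
    blood: BloodInput,
    schedule: FrameSchedule,
    six_class: bool = False,
    with_background_frame: bool = False,
    return_areas: bool = False,
):
    """Synthetic population class set generated by the 2TCM forward model.

    The published Turkheimer/VUMC/TPC class curves are not distributed;
    these stand-ins share their structure (one low- and one high-binding
    GM class, white matter, blood, optionally soft tissue and bone, and an
    optional leading 30-s background frame) so the SVCA machinery can be
    exercised and externally supplied sets swapped in via
    :func:`pkquant.io.read_class_set`.
    """
    names = list(BRAIN_CLASSES) + (list(EXTRACEREBRAL_CLASSES) if six_class else [])
    t = dense_grid(schedule)
    wb = blood.interp(t, "whole_blood", warn_extrapolate=False)
    curves = []
    for name in names:
        if name == "blood":
            curves.append(frame_average(t, wb, schedule))
        else:
            curves.append(simulate_2tcm(CLASS_KINETICS[name], blood, schedule).values)
    curves = np.vstack(curves)
    areas = curves @ schedule.durations  # absolute kBq/mL * min per class
    if with_background_frame:
        bg = 0.5
        sched = FrameSchedule(
            np.concatenate(([0.0], schedule.start_times + bg)),
            np.concatenate(([bg], schedule.end_times + bg)))
        curves = np.hstack([np.zeros((curves.shape[0], 1)) + 1e-3, curves])
        out = KineticClassSet(names, curves, sched, has_background_frame=True)
    else:
        out = KineticClassSet(names, curves, schedule)
    return (out, areas) if return_areas else out


def gen_voxel_dataset(
    classes: KineticClassSet,
    proportions,
    n_voxels: int,
    noise: NoiseModel | None = None,
    seed: int = 0,
    amplitude_mean: float = 10.0,
    class_amplitudes=None,
    amplitude_sigma: float = 0.2,
    mixture_fraction: float = 0.0,
    mixture_weights: tuple[float, float] = (0.6, 0.4),
    spatial_arrangement: str = "clustered",
    grid_shape: tuple[int, int, int] | None = None,
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    brain_mask=None,
) -> tuple[VoxelDataset, pd.DataFrame]:
    """Voxel population drawn from kinetic classes with known ground truth.

    Each voxel is one class curve — or, for a ``mixture_fraction`` of
    voxels, a two-class convex mixture — scaled by a log-normal amplitude,
    plus frame noise. ``class_amplitudes`` (one mean amplitude per class)
    puts voxels on each class's absolute concentration scale, e.g. the
    per-class curve areas from :func:`make_population_class_set`; without
    it every class shares ``amplitude_mean``. Returns the dataset and a
    truth table with the class label(s) and the true decomposition weights
    (area fractions) per voxel.
    """
    proportions = np.asarray(proportions, dtype=float)
    if proportions.size != classes.n_classes:
        raise ValueError("one proportion per class required")
    if abs(proportions.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    if n_voxels < classes.n_classes:
        raise ValueError("need at least as many voxels as classes")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    labels = rng.choice(classes.n_classes, size=n_voxels, p=proportions)
    if grid_shape is not None and spatial_arrangement == "clustered":
        # tissue classes are spatially contiguous in a brain; grouping the
        # labels keeps spatial smoothing from blending every class into
        # every voxel (class counts stay multinomial)
        labels = np.sort(labels)
    if class_amplitudes is None:
        class_amp = np.full(classes.n_classes, float(amplitude_mean))
    else:
        class_amp = np.asarray(class_amplitudes, dtype=float)
        if class_amp.shape != (classes.n_classes,):
            raise ValueError("one amplitude per class required")
    lognorm = np.exp(rng.normal(0.0, amplitude_sigma, n_voxels))
    is_mix = rng.random(n_voxels) < mixture_fraction
    true_w = np.zeros((n_voxels, classes.n_classes))
    mat = np.empty((n_voxels, classes.schedule.n_frames))
    rows = []
    for i in range(n_voxels):
        k = labels[i]
        raw_w = np.zeros(classes.n_classes)
        if is_mix[i]:
            other = int(rng.integers(classes.n_classes - 1))
            other = other + (other >= k)
            raw_w[k], raw_w[other] = mixture_weights
            second = classes.class_names[other]
        else:
            raw_w[k] = 1.0
            second = ""
        # area fractions of the unit-area decomposition (what NNLS sees)
        area_w = raw_w * class_amp
        true_w[i] = area_w / area_w.sum()
        curve = lognorm[i] * (area_w @ classes.curves)
        mat[i] = noise.apply(curve, classes.schedule, rng)
        rows.append({"voxel": i, "label": classes.class_names[k],
                     "second_label": second,
                     "amplitude": lognorm[i] * area_w.sum(),
                     **{f"w_{n}": true_w[i, j]
                        for j, n in enumerate(classes.class_names)}})
    ds = VoxelDataset(mat, classes.schedule, brain_mask=brain_mask,
                      voxel_size_mm=voxel_size_mm, grid_shape=grid_shape)
    return ds, pd.DataFrame(rows)
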