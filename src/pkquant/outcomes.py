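"""Outcome measures: distribution volumes, binding potential, SUV windows.

Macro parameters from 2TCM rate constants:

    BP_ND = k3 / k4
    V_T   = (K1 / k2) * (1 + k3 / k4)
    V_S   = K1 * k3 / (k2 * k4)        (so V_S = V_T - K1/k2)

SUV = mean tissue concentration over a time window divided by injected
dose per body weight; with activity in kBq/mL, dose in MBq and weight in
kg the kilo-prefixes cancel and SUV is in g/mL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import TAC
from .tcm import TwoTCMParams

__all__ = ["MacroOutcomes", "SUVWindow", "derive_macro", "compute_suv",
           "SUV_WINDOWS"]


@dataclass(frozen=True)
class MacroOutcomes:
    V_T: float  # mL/cm^3
    V_S: float  # mL/cm^3
    BP_ND: float  # unitless


@dataclass(frozen=True)
class SUVWindow:
    start: float = 40.0
    end: float = 60.0

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError("window must satisfy 0 <= start < end")

    @property
    def label(self) -> str:
        return f"{self.start:g}-{self.end:g}min"


#: the study's primary window plus the three alternative intervals
SUV_WINDOWS = (SUVWindow(40, 60), SUVWindow(10, 30),
               SUVWindow(20, 40), SUVWindow(30, 50))


def derive_macro(params: TwoTCMParams) -> MacroOutcomes:
    if params.k2 <= 0:
        raise ValueError("k2 must be positive")
    if params.k3 > 0 and params.k4 <= 0:
        raise ValueError("irreversible binding (k3 > 0, k4 = 0) has no V_T")
    bp = params.k3 / params.k4 if params.k3 > 0 else 0.0
    vnd = params.K1 / params.k2
    return MacroOutcomes(V_T=vnd * (1.0 + bp), V_S=vnd * bp, BP_ND=bp)


def compute_suv(tac: TAC, window: SUVWindow,
                injected_dose_MBq: float, body_weight_kg: float) -> float:
    """Time-weighted mean concentration in the window, dose-normalised.

    Frames partially inside the window contribute with fractional-overlap
    weights; a window truncated by a short scan (e.g. 40-60 min on a
    50-min acquisition) is computed over the covered portion with a
    warning.
    """
    if injected_dose_MBq <= 0 or body_weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    sched = tac.schedule
    overlap = np.clip(np.minimum(sched.end_times, window.end) -
                      np.maximum(sched.start_times, window.start), 0.0, None)
    total = overlap.sum()
    if total <= 0:
        raise ValueError(
            f"window {window.label} does not overlap the scan")
    if total < (window.end - window.start) - 1e-9:
        warnings.warn(
            f"window {window.label} only partially covered by the scan "
            "(short-scan); SUV computed over the covered portion",
            stacklevel=2)
    mean_conc = float(tac.values @ overlap / total)
    return mean_conc * body_weight_kg / injected_dose_MBq
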