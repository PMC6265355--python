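"""Internal-arithmetic checks on the published summary tables.

The human cohort data behind the published tables are not distributed, so
the reproducible part of those results is their internal arithmetic: the
reported medians must equal the medians of the reported per-region cells,
and every SEM / MD% cell must follow from its row's mean, SD and ICC via

    SEM = SD * sqrt(1 - ICC),   MD% = 100 * 1.96 * sqrt(2) * SEM / |mean|.

Because the published cells are rounded, a point recomputation from the
rounded inputs can differ from the printed cell by more than the cell's
own rounding step. Each cell is therefore checked for *interval
consistency*: the printed value (within half a ULP of its printed
precision) must be attainable by the formula evaluated over the half-ULP
rounding intervals of its printed inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .reliability import MD_FACTOR, sem_from

__all__ = ["load_table1", "load_table2", "load_reported_summaries",
           "reproduce_checks", "ChecksReport"]

TARGET_REGIONS_T1 = ("FC", "GM", "HIP", "STR", "THAL")


def _data_path(name: str):
    return resources.files("pkquant").joinpath("data", name)


def load_table1() -> pd.DataFrame:
    with resources.as_file(_data_path("table1.csv")) as p:
        return pd.read_csv(p)


def load_table2() -> pd.DataFrame:
    with resources.as_file(_data_path("table2.csv")) as p:
        return pd.read_csv(p)


def load_reported_summaries() -> dict:
    return json.loads(_data_path("reported_summaries.json").read_text())


@dataclass
class ChecksReport:
    table: pd.DataFrame  # check, recomputed, reported, passed

    @property
    def all_passed(self) -> bool:
        return bool(self.table["passed"].all())

    def value(self, check: str) -> float:
        row = self.table[self.table["check"] == check]
        if row.empty:
            raise KeyError(check)
        return float(row["recomputed"].iloc[0])


def _sem_interval(sd, icc, ulp=0.005):
    lo = max(sd - ulp, 0.0) * np.sqrt(1.0 - min(icc + ulp, 1.0))
    hi = (sd + ulp) * np.sqrt(1.0 - (icc - ulp))
    return lo, hi


def _md_interval(sem_lo, sem_hi, mean, mean_ulp=0.005):
    amean = abs(mean)
    lo = 100.0 * MD_FACTOR * sem_lo / (amean + mean_ulp)
    denom = max(amean - mean_ulp, 1e-12)
    hi = 100.0 * MD_FACTOR * sem_hi / denom
    return lo, hi


def _row_checks(rows, label_cols, out):
    for _, row in rows.iterrows():
        label = "/".join(str(row[c]) for c in label_cols)
        sem_pt = sem_from(row["sd"], row["icc"])
        md_pt = 100.0 * MD_FACTOR * sem_pt / abs(row["mean"])
        slo, shi = _sem_interval(row["sd"], row["icc"])
        mlo, mhi = _md_interval(slo, shi, row["mean"])
        out.append({
            "check": f"sem[{label}]", "recomputed": sem_pt,
            "reported": row["sem"],
            "passed": slo - 0.005 <= row["sem"] <= shi + 0.005,
        })
        out.append({
            "check": f"md_pct[{label}]", "recomputed": md_pt,
            "reported": row["md_pct"],
            "passed": mlo - 0.5 <= row["md_pct"] <= mhi + 0.5,
        })


def reproduce_checks(
    table1: pd.DataFrame | None = None,
    table2: pd.DataFrame | None = None,
    summaries: dict | None = None,
) -> ChecksReport:
    """Recompute the published tables' internal arithmetic; report pass/fail.

    Custom (e.g. perturbed) tables may be passed in to verify that the
    harness actually detects inconsistencies.
    """
    t1 = load_table1() if table1 is None else table1
    t2 = load_table2() if table2 is None else table2
    rep = load_reported_summaries() if summaries is None else summaries
    out: list[dict] = []

    for outcome, reported in rep["median_icc"].items():
        med = float(t1.loc[t1["outcome"] == outcome, "icc"].median())
        out.append({"check": f"median_icc[{outcome}]", "recomputed": med,
                    "reported": reported,
                    "passed": abs(med - reported) < 1e-9})
    for outcome, reported in rep["median_md_pct"].items():
        med = float(t1.loc[t1["outcome"] == outcome, "md_pct"].median())
        out.append({"check": f"median_md_pct[{outcome}]", "recomputed": med,
                    "reported": reported,
                    "passed": abs(med - reported) < 1e-9})

    _row_checks(t1, ["outcome", "region"], out)
    _row_checks(t2, ["method", "outcome"], out)

    mean_2tcm = t1.loc[t1["outcome"] == "BP_ND (2TCM)", "mean"].mean()
    mean_svca = t1.loc[t1["outcome"] == "BP_ND (SRTM-SVCA4)", "mean"].mean()
    ratio = float(mean_2tcm / mean_svca)
    reported_ratio = rep["bpnd_region_mean_ratio"]["2TCM_over_SRTM-SVCA4"]
    out.append({"check": "bpnd_ratio_2tcm_over_srtm_svca4",
                "recomputed": ratio, "reported": reported_ratio,
                "passed": ratio > reported_ratio})

    return ChecksReport(pd.DataFrame(out))
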