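"""Test-retest reliability and convergent-validity statistics.

Metrics for a two-session design with n subjects:

* ICC: one-way random-effects, single-measure. From the one-way ANOVA
  with subjects as groups and k = 2 measurements per subject,
  ``ICC = (MSB - MSW) / (MSB + MSW)``; negative estimates are reported
  as-is (they occur whenever within-subject scatter exceeds
  between-subject scatter).
* AbsVar%: mean over subjects of ``100 * |x1 - x2| / ((x1 + x2) / 2)``.
* SEM: ``SD * sqrt(1 - ICC)``, with SD pooled over all 2n values; a
  negative ICC legitimately gives SEM > SD.
* MD%: minimum detectable difference, ``1.96 * sqrt(2) * SEM``, as a
  percentage of the absolute pooled mean.

Convergent validity: Pearson r (and R^2) between outcome pairs with
subject x session x region values pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import StudyTable

__all__ = ["icc_oneway", "absvar_pct", "sem_from", "md_pct_from",
           "summarize_trt", "median_summary", "validity_matrix"]

log = logging.getLogger(__name__)

MD_FACTOR = 1.96 * np.sqrt(2.0)


def _as_pairs(pairs) -> np.ndarray:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (test, retest)")
    return arr


def icc_oneway(pairs) -> float:
    """One-way random-effects single-measure ICC for k = 2 sessions."""
    arr = _as_pairs(pairs)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects with both sessions")
    grand = arr.mean()
    subj_means = arr.mean(axis=1)
    msb = 2.0 * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((arr - subj_means[:, None]) ** 2) / n
    if msb + msw == 0:
        raise ValueError("zero total variance: ICC undefined")
    return float((msb - msw) / (msb + msw))


def icc_oneway_many(x1: np.ndarray, x2: np.ndarray, axis: int = 0) -> np.ndarray:
    """Vectorised icc_oneway over stacked replicate studies."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    n = x1.shape[axis]
    m = 0.5 * (x1 + x2)
    grand = m.mean(axis=axis, keepdims=True)
    msb = 2.0 * ((m - grand) ** 2).sum(axis=axis) / (n - 1)
    msw = ((x1 - m) ** 2 + (x2 - m) ** 2).sum(axis=axis) / n
    return (msb - msw) / (msb + msw)


def absvar_pct(pairs) -> float:
    """Average absolute test-retest difference as % of the pair mean."""
    arr = _as_pairs(pairs)
    mean = arr.mean(axis=1)
    ok = mean != 0
    if not ok.all():
        log.warning("absvar_pct: %d pair(s) with zero mean excluded",
                    int((~ok).sum()))
    if not ok.any():
        raise ValueError("all pair means are zero")
    return float(np.mean(100.0 * np.abs(arr[ok, 0] - arr[ok, 1]) / np.abs(mean[ok])))


def sem_from(sd: float, icc: float) -> float:
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    if icc > 1:
        raise ValueError("icc cannot exceed 1")
    return float(sd * np.sqrt(1.0 - icc))


def md_pct_from(sem: float, mean: float) -> float:
    if mean == 0:
        raise ValueError("MD%% undefined for zero mean")
    return float(100.0 * MD_FACTOR * sem / abs(mean))


@dataclass
class TrtMetrics:
    """Per (outcome, region) table of test-retest metrics."""

    table: pd.DataFrame  # columns: outcome, region, n, mean, sd, icc, absvar_pct, sem, md_pct


def summarize_trt(study: StudyTable) -> TrtMetrics:
    """Reliability metrics per (outcome, region).

    Mean and SD pool all subject-session values (2n of them); subjects
    missing a session are dropped with a log entry.
    """
    rows = []
    df = study.data
    for (outcome, region), _ in df.groupby(["outcome", "region"]):
        wide = study.pairs(outcome, region)
        n_all = df[(df["outcome"] == outcome) &
                   (df["region"] == region)]["subject_id"].nunique()
        if len(wide) < n_all:
            log.info("%s/%s: dropped %d incomplete subject(s)",
                     outcome, region, n_all - len(wide))
        if len(wide) < 2:
            raise ValueError(
                f"{outcome}/{region}: fewer than two complete subjects")
        arr = wide[["test", "retest"]].to_numpy()
        pooled = arr.ravel()
        mean, sd = float(pooled.mean()), float(pooled.std(ddof=1))
        icc = icc_oneway(arr)
        sem = sem_from(sd, icc)
        rows.append({
            "outcome": outcome, "region": region, "n": len(wide),
            "mean": mean, "sd": sd, "icc": icc,
            "absvar_pct": absvar_pct(arr), "sem": sem,
            "md_pct": md_pct_from(sem, mean),
        })
    table = pd.DataFrame(rows)
    # internal identities hold by construction; assert them on every summary
    assert np.allclose(table["sem"], table["sd"] * np.sqrt(1 - table["icc"]))
    assert np.allclose(table["md_pct"],
                       100 * MD_FACTOR * table["sem"] / table["mean"].abs())
    return TrtMetrics(table)


def median_summary(metrics: TrtMetrics | pd.DataFrame, metric: str,
                   outcome: str, regions=None) -> float:
    """Median of one metric over regions for one outcome."""
    table = metrics.table if isinstance(metrics, TrtMetrics) else metrics
    sub = table[table["outcome"] == outcome]
    if regions is not None:
        sub = sub[sub["region"].isin(regions)]
    if sub.empty:
        raise ValueError(f"no rows for outcome {outcome!r}")
    return float(sub[metric].median())


@dataclass
class ValidityMatrix:
    """Pooled Pearson correlations between outcome pairs."""

    outcomes: list[str]
    r: pd.DataFrame
    n: pd.DataFrame

    @property
    def r2(self) -> pd.DataFrame:
        return self.r ** 2


def validity_matrix(study: StudyTable, outcomes=None) -> ValidityMatrix:
    """Pearson r between outcomes, pooling subjects, sessions and regions."""
    df = study.data
    if outcomes is None:
        outcomes = study.outcomes
    wide = df[df["outcome"].isin(outcomes)].pivot_table(
        index=["subject_id", "session", "region"], columns="outcome",
        values="value")
    wide = wide.reindex(columns=outcomes)
    r = pd.DataFrame(np.eye(len(outcomes)), index=outcomes, columns=outcomes)
    n = pd.DataFrame(0, index=outcomes, columns=outcomes, dtype=int)
    for i, a in enumerate(outcomes):
        n.loc[a, a] = int(wide[a].notna().sum())
        for b in outcomes[i + 1:]:
            sub = wide[[a, b]].dropna()
            if len(sub) < 3:
                raise ValueError(f"fewer than 3 pooled points for {a} vs {b}")
            if sub[a].std() == 0 or sub[b].std() == 0:
                log.warning("constant outcome in pair (%s, %s): r undefined", a, b)
                rv = np.nan
            else:
                rv = float(np.corrcoef(sub[a], sub[b])[0, 1])
            r.loc[a, b] = r.loc[b, a] = rv
            n.loc[a, b] = n.loc[b, a] = len(sub)
    return ValidityMatrix(list(outcomes), r, n)
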