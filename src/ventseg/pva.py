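"""Per-breath feature tables and definition-based asynchrony classification.

A breath is the interval between consecutive inspiratory onsets (the cycling
convention of the reference standard).  From the onsets and the flow channel
the module derives, per breath:

* Ti — inspiratory duration, (exp_onset - insp_onset) / rate, s;
* Te — expiratory duration, (next_insp_onset - exp_onset) / rate, s;
* TVi / TVe — inhaled / exhaled tidal volume, mL, by trapezoidal integration
  of the positive (resp. negative) part of flow over the corresponding phase
  (flow L/min -> mL/s conversion x 1000/60);
* ratio — TVe/TVi.

Three published definitions are applied:

* double trigger, definition 1: Te < 50% of the mean inspiratory time
  (mean over the analyzed cohort, strict <);
* double trigger, definition 2: Te <= 0.3 s and (TVe/TVi < 0.25, or
  TVe/TVi < 0.50 with TVe < 100 mL);
* stacked breath: Te > 0.3 s and TVe/TVi < 0.9.

Frequencies across segmentation sources are compared with Pearson
chi-squared tests (2x2, no continuity correction).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError, OnsetAnnotation, WaveformRecord

__all__ = [
    "BreathRow",
    "PVAReport",
    "breath_table",
    "classify_dt_def1",
    "classify_dt_def2",
    "classify_stacked",
    "pva_report",
    "compare_frequencies",
    "chi_squared_2x2",
    "welch_ttest",
]

logger = logging.getLogger(__name__)

_ML_PER_LMIN = 1000.0 / 60.0  # L/min -> mL/s


@dataclass
class BreathRow:
    insp_onset: int
    exp_onset: int
    next_insp_onset: int
    ti: float
    te: float
    tvi: float
    tve: float
    ratio: float
    btype: str | None = None


@dataclass
class PVAReport:
    """Counts and frequencies of asynchronous breaths for one segmentation source."""

    source: str
    n_breaths: int
    dt_def1: int
    dt_def2: int
    stacked: int
    n_excluded: int = 0

    @property
    def frequencies(self) -> dict[str, float]:
        n = max(self.n_breaths, 1)
        return {
            "dt_def1": self.dt_def1 / n,
            "dt_def2": self.dt_def2 / n,
            "stacked": self.stacked / n,
        }

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "n_breaths": self.n_breaths,
            "n_excluded": self.n_excluded,
            "counts": {"dt_def1": self.dt_def1, "dt_def2": self.dt_def2, "stacked": self.stacked},
            "frequencies": self.frequencies,
        }


def breath_table(record: WaveformRecord, annotation: OnsetAnnotation) -> pd.DataFrame:
    """Per-breath feature table from onset indices and the flow channel.

    Breaths lacking an expiratory onset or a successor inspiratory onset are
    dropped (their count is logged and available as ``df.attrs['n_dropped']``).
    """
    if record.flow is None or not len(record.flow):
        raise DataError("record has no flow channel")
    annotation.validate(len(record), pairing=False)
    flow_mls = record.flow * _ML_PER_LMIN
    rate = record.sample_rate
    exp_per_breath = annotation.exp_for_breath()
    insp = annotation.insp_onsets
    btypes = annotation.breath_types

    rows, dropped = [], 0
    for k in range(len(insp)):
        if k + 1 >= len(insp) or exp_per_breath[k] < 0:
            dropped += 1
            continue
        a, b, c = int(insp[k]), int(exp_per_breath[k]), int(insp[k + 1])
        tvi = np.trapezoid(np.clip(flow_mls[a : b + 1], 0, None), dx=1.0 / rate)
        tve = np.trapezoid(np.clip(-flow_mls[b : c + 1], 0, None), dx=1.0 / rate)
        rows.append(
            dict(
                insp_onset=a,
                exp_onset=b,
                next_insp_onset=c,
                ti=(b - a) / rate,
                te=(c - b) / rate,
                tvi=tvi,
                tve=tve,
                ratio=tve / tvi if tvi > 0 else np.nan,
                btype=str(btypes[k]) if btypes is not None else None,
            )
        )
    if dropped:
        logger.info("breath_table: dropped %d breath(s) without exp onset or successor", dropped)
    df = pd.DataFrame(
        rows,
        columns=["insp_onset", "exp_onset", "next_insp_onset", "ti", "te", "tvi", "tve", "ratio", "btype"],
    )
    df.attrs["n_dropped"] = dropped
    return df


def _require_rows(rows: pd.DataFrame) -> pd.DataFrame:
    if not len(rows):
        raise DataError("empty breath table")
    bad = ~(rows["tvi"] > 0)
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} breath(s) with TVi <= 0", stacklevel=3)
    return rows


def classify_dt_def1(rows: pd.DataFrame) -> pd.Series:
    """Double trigger, definition 1: Te < 0.5 x mean Ti of the cohort."""
    rows = _require_rows(rows)
    mean_ti = rows["ti"].mean()
    return rows["te"] < 0.5 * mean_ti


def classify_dt_def2(rows: pd.DataFrame) -> pd.Series:
    """Double trigger, definition 2: Te <= 0.3 s with low exhaled volume."""
    rows = _require_rows(rows)
    valid = rows["tvi"] > 0
    flag = (rows["te"] <= 0.3) & (
        (rows["ratio"] < 0.25) | ((rows["ratio"] < 0.50) & (rows["tve"] < 100.0))
    )
    return flag & valid


def classify_stacked(rows: pd.DataFrame) -> pd.Series:
    """Stacked breath: Te > 0.3 s with TVe/TVi < 0.9."""
    rows = _require_rows(rows)
    valid = rows["tvi"] > 0
    return (rows["te"] > 0.3) & (rows["ratio"] < 0.9) & valid


def pva_report(record: WaveformRecord, annotation: OnsetAnnotation, source: str) -> PVAReport:
    """Classify every breath of a record under all three definitions."""
    rows = breath_table(record, annotation)
    if not len(rows):
        return PVAReport(source=source, n_breaths=0, dt_def1=0, dt_def2=0, stacked=0,
                         n_excluded=rows.attrs.get("n_dropped", 0))
    return PVAReport(
        source=source,
        n_breaths=len(rows),
        dt_def1=int(classify_dt_def1(rows).sum()),
        dt_def2=int(classify_dt_def2(rows).sum()),
        stacked=int(classify_stacked(rows).sum()),
        n_excluded=rows.attrs.get("n_dropped", 0),
    )


def chi_squared_2x2(table) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no Yates correction) on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise DataError("expected a 2x2 contingency table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("zero margin in contingency table; returning p = 1", stacklevel=2)
        return 0.0, 1.0
    stat, p, _dof, _exp = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def compare_frequencies(report_a: PVAReport, report_b: PVAReport) -> dict[str, dict[str, float]]:
    """Per-category chi-squared comparison of two asynchrony reports."""
    out = {}
    for category in ("dt_def1", "dt_def2", "stacked"):
        a_yes = getattr(report_a, category)
        b_yes = getattr(report_b, category)
        table = [
            [a_yes, report_a.n_breaths - a_yes],
            [b_yes, report_b.n_breaths - b_yes],
        ]
        stat, p = chi_squared_2x2(table)
        out[category] = {"chi2": stat, "p": p}
    return out


def welch_ttest(a, b) -> tuple[float, float]:
    """Two-sided Welch t-test for continuous per-breath features."""
    stat, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(stat), float(p)
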