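"""Event matching and detection metrics against a reference standard.

Predicted onsets are matched one-to-one to reference onsets within a sample
tolerance (0 = exact-timepoint matching; 0.1 s = 5 samples at 50 Hz,
inclusive).  The default matcher pairs events greedily in increasing order of
absolute offset, ties broken toward the earlier reference event; an
optimal-assignment mode (max cardinality, then minimum total offset, via the
Hungarian algorithm) is available for cross-checks.  The two coincide
whenever reference events are separated by more than twice the tolerance,
which holds for breath onsets (breaths last ~50 samples, tolerance 5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm

from .core import DataError, OnsetAnnotation

__all__ = [
    "EventMatchResult",
    "match_events",
    "prf1",
    "stratified_eval",
    "required_sample_size",
]


@dataclass
class EventMatchResult:
    tp: int
    fp: int
    fn: int
    matches: list = field(default_factory=list)  # (ref index, pred index, offset)
    tolerance: int = 0


def match_events(
    reference,
    predicted,
    tolerance: int,
    method: str = "greedy",
) -> EventMatchResult:
    """One-to-one matching of predicted to reference onsets.

    ``tolerance`` is inclusive and in samples.  ``method='greedy'`` pairs in
    increasing order of |offset| with earlier-reference tie-breaking;
    ``method='optimal'`` solves the assignment maximizing matched pairs and,
    among those, minimizing the total absolute offset.
    """
    ref = np.asarray(reference, dtype=np.int64)
    pred = np.asarray(predicted, dtype=np.int64)
    if np.any(np.diff(ref) < 0) or np.any(np.diff(pred) < 0):
        raise DataError("event lists must be sorted")
    if tolerance < 0:
        raise DataError("tolerance must be non-negative")

    if method == "greedy":
        pairs = [
            (abs(int(r) - int(p)), i, j)
            for i, r in enumerate(ref)
            for j, p in enumerate(pred)
            if abs(int(r) - int(p)) <= tolerance
        ]
        pairs.sort()  # by |offset|, then earlier reference, then earlier predicted
        used_ref, used_pred, matches = set(), set(), []
        for off, i, j in pairs:
            if i in used_ref or j in used_pred:
                continue
            used_ref.add(i)
            used_pred.add(j)
            matches.append((int(ref[i]), int(pred[j]), int(pred[j]) - int(ref[i])))
    elif method == "optimal":
        big = (tolerance + 1.0) * (len(ref) + len(pred) + 1)
        cost = np.abs(ref[:, None] - pred[None, :]).astype(float)
        cost[cost > tolerance] = big
        matches = []
        if cost.size:
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] <= tolerance:
                    matches.append((int(ref[i]), int(pred[j]), int(pred[j]) - int(ref[i])))
        matches.sort()
    else:
        raise ValueError(f"unknown matching method '{method}'")

    tp = len(matches)
    return EventMatchResult(
        tp=tp, fp=len(pred) - tp, fn=len(ref) - tp, matches=matches, tolerance=tolerance
    )


def prf1(result: EventMatchResult) -> tuple[float, float, float]:
    """Precision, recall and F1; empty denominators yield 0 with a warning."""
    tp, fp, fn = result.tp, result.fp, result.fn
    if tp + fp == 0 or tp + fn == 0 or tp == 0:
        if tp + fp == 0 or tp + fn == 0:
            warnings.warn("degenerate counts: empty denominator treated as 0", stacklevel=2)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        return precision, recall, 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return precision, recall, 2 * precision * recall / (precision + recall)


def _breath_stratum(annotation: OnsetAnnotation) -> np.ndarray:
    types = annotation.coarse_types()
    if types is None:
        raise DataError("stratified evaluation requires reference breath_types")
    return types


def stratified_eval(
    reference: OnsetAnnotation,
    predicted: OnsetAnnotation,
    tolerance: int,
    method: str = "greedy",
) -> pd.DataFrame:
    """Per-breath-type metric table (normal / pva / artifact / pooled).

    Every event — reference or predicted, matched or not — is assigned to the
    stratum of its enclosing reference breath (the interval between
    consecutive reference inspiratory onsets), so per-stratum true-positive
    counts partition the pooled counts exactly.
    """
    strata = _breath_stratum(reference)
    insp = reference.insp_onsets
    if insp.size == 0:
        raise DataError("reference annotation has no breaths")

    def stratum_of(sample: int) -> str:
        k = int(np.searchsorted(insp, sample, side="right")) - 1
        k = min(max(k, 0), len(strata) - 1)
        return str(strata[k])

    rows = []
    for onset_type, ref_events, pred_events in (
        ("insp", reference.insp_onsets, predicted.insp_onsets),
        ("exp", reference.exp_onsets, predicted.exp_onsets),
    ):
        result = match_events(ref_events, pred_events, tolerance, method=method)
        matched_ref = {m[0] for m in result.matches}
        matched_pred = {m[1] for m in result.matches}
        counts = {s: {"tp": 0, "fp": 0, "fn": 0} for s in ("normal", "pva", "artifact")}
        for r, p, _off in result.matches:
            counts[stratum_of(r)]["tp"] += 1
        for r in ref_events:
            if int(r) not in matched_ref:
                counts[stratum_of(int(r))]["fn"] += 1
        for p in pred_events:
            if int(p) not in matched_pred:
                counts[stratum_of(int(p))]["fp"] += 1
        for stratum, c in counts.items():
            res = EventMatchResult(c["tp"], c["fp"], c["fn"], tolerance=tolerance)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                precision, recall, f1 = prf1(res)
            rows.append(
                dict(onset_type=onset_type, stratum=stratum, **c,
                     precision=precision, recall=recall, f1=f1)
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            precision, recall, f1 = prf1(result)
        rows.append(
            dict(onset_type=onset_type, stratum="pooled", tp=result.tp, fp=result.fp,
                 fn=result.fn, precision=precision, recall=recall, f1=f1)
        )
    return pd.DataFrame(rows)


def required_sample_size(
    p0: float, p1: float, power: float = 0.8, alpha: float = 0.05, pooled: bool = False
) -> int:
    """Per-group n to detect a change in proportion p0 -> p1 (two-sided).

    Default is the unpooled two-sample normal approximation

        n = ceil( (z_{1-alpha/2} + z_{power})^2 (p0 q0 + p1 q1) / (p1-p0)^2 );

    ``pooled=True`` uses the Fleiss pooled-variance variant instead.
    """
    for name, v in (("p0", p0), ("p1", p1), ("power", power), ("alpha", alpha)):
        if not (0 < v < 1):
            raise DataError(f"{name} must lie strictly between 0 and 1")
    if p0 == p1:
        raise DataError("p0 and p1 must differ")
    z_a = norm.ppf(1 - alpha / 2)
    z_b = norm.ppf(power)
    delta = abs(p1 - p0)
    if pooled:
        pbar = (p0 + p1) / 2
        n = (z_a * np.sqrt(2 * pbar * (1 - pbar)) + z_b * np.sqrt(p0 * (1 - p0) + p1 * (1 - p1))) ** 2 / delta**2
    else:
        n = (z_a + z_b) ** 2 * (p0 * (1 - p0) + p1 * (1 - p1)) / delta**2
    return int(np.ceil(n - 1e-12))
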