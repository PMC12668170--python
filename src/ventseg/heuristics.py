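"""Rule-based breath-segmentation baselines.

Two published heuristics are reproduced from their textual descriptions
(source code for the originals is not public), plus the candidate-generation
rule used when building an expiratory-onset reference standard:

* zero crossing — inspiratory onset whenever flow crosses from negative to
  positive, expiratory onset on the opposite crossing; deliberately naive
  (no debouncing, no pairing), which is its documented failure mode in noise;
* derivative backtracking — anchor on flow > 12 L/min (inspiration) or
  sustained flow < -5 L/min (expiration) and step backward along the first
  difference of flow to where the derivative "began to change" (sign change
  or magnitude below a plateau tolerance);
* reference expiratory candidates — the zero crossing following the largest
  positive continuous area under the flow curve within each breath interval.

Crossing convention: a crossing belongs to the first sample on the new
sign's side; exact zeros count with the non-negative side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .core import DataError, OnsetAnnotation, WaveformRecord

__all__ = [
    "HeuristicParams",
    "zero_crossing_segment",
    "derivative_backtrack_insp",
    "derivative_backtrack_exp",
    "reference_exp_candidates",
    "ZeroCrossingSegmenter",
    "DerivativeBacktrackSegmenter",
]


@dataclass
class HeuristicParams:
    insp_flow_threshold: float = 12.0  # L/min
    exp_flow_threshold: float = -5.0  # L/min
    exp_persistence: float = 0.025  # s the flow must stay negative
    derivative_eps: float = 0.5  # L/min per sample; plateau tolerance

    def __post_init__(self):
        if not (self.insp_flow_threshold > 0 > self.exp_flow_threshold):
            raise DataError("need insp_flow_threshold > 0 > exp_flow_threshold")
        if self.exp_persistence < 0:
            raise DataError("exp_persistence must be non-negative")


def zero_crossing_segment(record: WaveformRecord) -> OnsetAnnotation:
    """Label every sign crossing of flow; no pairing or debouncing applied."""
    flow = record.flow
    if len(flow) < 2:
        raise DataError("record must contain at least 2 samples")
    prev, cur = flow[:-1], flow[1:]
    insp = np.nonzero((prev < 0) & (cur >= 0))[0] + 1
    exp = np.nonzero((prev > 0) & (cur <= 0))[0] + 1
    return OnsetAnnotation(insp, exp)


def _backtrack(flow: np.ndarray, start: int, floor: int, eps: float) -> int:
    """Walk backward from `start` while the first difference keeps the sign of
    the step into `start` and magnitude > eps; return the sample where the
    derivative began to change (never below `floor`)."""
    d0 = flow[start] - flow[start - 1] if start >= 1 else 0.0
    if abs(d0) <= eps:
        return max(start - 1, floor)
    sign = np.sign(d0)
    i = start
    while i - 1 > floor:
        d = flow[i - 1] - flow[i - 2]
        if np.sign(d) != sign or abs(d) <= eps:
            return i - 1
        i -= 1
    return floor


def derivative_backtrack_insp(
    record: WaveformRecord, params: HeuristicParams | None = None
) -> np.ndarray:
    """Inspiratory onsets: backtrack from each run of flow above threshold."""
    params = params or HeuristicParams()
    flow = record.flow
    if len(flow) < 3:
        raise DataError("record must contain at least 3 samples")
    above = flow > params.insp_flow_threshold
    # first index of each maximal run of suprathreshold flow
    run_starts = np.nonzero(above & ~np.concatenate([[False], above[:-1]]))[0]
    onsets = {int(_backtrack(flow, int(s), 0, params.derivative_eps)) for s in run_starts}
    return np.array(sorted(onsets), dtype=np.int64)


def derivative_backtrack_exp(
    record: WaveformRecord,
    insp_onsets: np.ndarray,
    params: HeuristicParams | None = None,
) -> np.ndarray:
    """Expiratory onsets: at most one per inspiratory interval.

    Within each interval, find the first sample below the expiratory flow
    threshold whose following ``ceil(persistence * rate)`` samples are all
    negative, then backtrack to the nearest earlier sample where flow is
    non-negative or the first difference has plateaued.
    """
    params = params or HeuristicParams()
    flow = record.flow
    n = len(flow)
    insp_onsets = np.asarray(insp_onsets, dtype=np.int64)
    persist = int(np.ceil(params.exp_persistence * record.sample_rate))
    # eligible[t]: flow[t] below threshold and the following `persist` samples
    # all negative (and present)
    neg = (flow < 0).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(neg)])
    eligible = flow < params.exp_flow_threshold
    if persist > 0:
        tail_ok = np.zeros(n, dtype=bool)
        valid = np.arange(n) + persist < n
        idx = np.nonzero(valid)[0]
        tail_ok[idx] = (cum[idx + 1 + persist] - cum[idx + 1]) == persist
        eligible &= tail_ok
    onsets = []
    bounds = list(insp_onsets) + [n]
    for a, b in zip(bounds[:-1], bounds[1:]):
        hits = np.nonzero(eligible[a + 1 : b])[0]
        if not hits.size:
            continue
        found = int(a + 1 + hits[0])
        u = found
        while u - 1 > a:
            u -= 1
            if flow[u] >= 0 or abs(flow[u] - flow[u - 1]) <= params.derivative_eps:
                break
        if a < u < b:
            onsets.append(int(u))
    return np.array(sorted(set(onsets)), dtype=np.int64)


def reference_exp_candidates(record: WaveformRecord, insp_onsets: np.ndarray) -> np.ndarray:
    """Zero crossing after the largest positive-area flow lobe of each breath."""
    flow = record.flow
    insp_onsets = np.asarray(insp_onsets, dtype=np.int64)
    if insp_onsets.size < 1:
        raise DataError("need at least one inspiratory onset")
    dt = 1.0 / record.sample_rate
    candidates = []
    bounds = list(insp_onsets) + [len(flow)]
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = flow[a:b]
        pos = seg > 0
        if not np.any(pos):
            continue
        edges = np.diff(pos.astype(np.int8))
        starts = list(np.nonzero(edges == 1)[0] + 1)
        ends = list(np.nonzero(edges == -1)[0] + 1)
        if pos[0]:
            starts = [0] + starts
        if pos[-1]:
            ends = ends + [len(seg)]
        best_end, best_area = None, -np.inf
        for s, e in zip(starts, ends):
            area = np.trapezoid(seg[s:e], dx=dt)
            if area > best_area:
                best_area, best_end = area, e
        if best_end is not None and best_end < len(seg):
            # first sample on the non-positive side after the winning lobe
            candidates.append(int(a + best_end))
    return np.array(candidates, dtype=np.int64)


class ZeroCrossingSegmenter(BaseEstimator):
    """Parameter-free zero-crossing baseline (scikit-learn estimator shell)."""

    def fit(self, records=None, y=None):
        self.fitted_ = True
        return self

    def predict(self, record: WaveformRecord) -> OnsetAnnotation:
        return zero_crossing_segment(record)


class DerivativeBacktrackSegmenter(BaseEstimator):
    """Derivative-backtracking baseline with its published thresholds."""

    def __init__(
        self,
        insp_flow_threshold: float = 12.0,
        exp_flow_threshold: float = -5.0,
        exp_persistence: float = 0.025,
        derivative_eps: float = 0.5,
    ):
        self.insp_flow_threshold = insp_flow_threshold
        self.exp_flow_threshold = exp_flow_threshold
        self.exp_persistence = exp_persistence
        self.derivative_eps = derivative_eps

    def _params(self) -> HeuristicParams:
        return HeuristicParams(
            insp_flow_threshold=self.insp_flow_threshold,
            exp_flow_threshold=self.exp_flow_threshold,
            exp_persistence=self.exp_persistence,
            derivative_eps=self.derivative_eps,
        )

    def fit(self, records=None, y=None):
        self.fitted_ = True
        return self

    def predict(self, record: WaveformRecord) -> OnsetAnnotation:
        params = self._params()
        insp = derivative_backtrack_insp(record, params)
        exp = derivative_backtrack_exp(record, insp, params)
        return OnsetAnnotation(insp, exp)
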