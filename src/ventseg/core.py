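"""Data model, file I/O, sliding-window extraction and per-window normalization
for two-channel (airway pressure, flow) ventilator waveforms sampled at 50 Hz.

Conventions used throughout the package:

* indices are 0-based; windows are half-open ``[start, start + len)``;
* an onset (inspiratory or expiratory) is a single sample index — labels are
  one-hot at one timestep per event, with no temporal smearing;
* the model input window is 352 samples (7.04 s at 50 Hz) and the supervised
  output spans the central 176 samples (3.52 s), so output spans tile a record
  without overlap at the default step of 176.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "DataError",
    "ConfigurationError",
    "LeakageError",
    "OnsetAnnotation",
    "WaveformRecord",
    "WindowBatch",
    "read_record",
    "write_record",
    "window_samples",
    "make_windows",
    "normalize_window",
]

#: coarse breath strata; fine-grained generator labels map onto these
COARSE_TYPES = ("normal", "pva", "artifact")
_FINE_TO_COARSE = {
    "normal": "normal",
    "pva": "pva",
    "double_trigger": "pva",
    "stacked": "pva",
    "artifact": "artifact",
}


class FormatError(ValueError):
    """A file does not conform to the expected columnar layout."""


class DataError(ValueError):
    """The data violate a structural invariant (e.g. non-uniform timestamps)."""


class ConfigurationError(ValueError):
    """Inconsistent configuration values."""


class LeakageError(ValueError):
    """Train/validation provenance overlap (split must be by patient)."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class OnsetAnnotation:
    """Ordered inspiratory/expiratory onset sample indices with breath types.

    ``breath_types`` is aligned to ``insp_onsets`` (one label per breath) and
    may carry the fine generator labels (``double_trigger``, ``stacked``);
    :meth:`coarse_types` folds these into ``normal | pva | artifact``.
    """

    insp_onsets: np.ndarray
    exp_onsets: np.ndarray
    breath_types: np.ndarray | None = None

    def __post_init__(self):
        self.insp_onsets = np.asarray(self.insp_onsets, dtype=np.int64)
        self.exp_onsets = np.asarray(self.exp_onsets, dtype=np.int64)
        if self.breath_types is not None:
            self.breath_types = np.asarray(self.breath_types, dtype=object)

    def validate(self, n_samples: int, pairing: bool = True) -> None:
        """Check structural invariants.

        With ``pairing=True`` also enforce the breath-cycle constraints: at
        most one expiratory onset between consecutive inspiratory onsets, and
        every expiratory onset strictly after the inspiratory onset of its
        breath.  Raw heuristic output (e.g. zero crossings) is validated with
        ``pairing=False`` since the naive rule guarantees neither.
        """
        for name, idx in (("insp_onsets", self.insp_onsets), ("exp_onsets", self.exp_onsets)):
            if idx.size and (np.any(np.diff(idx) <= 0)):
                raise DataError(f"{name} must be strictly increasing")
            if idx.size and (idx[0] < 0 or idx[-1] >= n_samples):
                raise DataError(f"{name} out of record bounds [0, {n_samples})")
        if self.breath_types is not None and len(self.breath_types) != len(self.insp_onsets):
            raise DataError("breath_types must align with insp_onsets")
        if pairing and self.insp_onsets.size:
            edges = np.concatenate([self.insp_onsets, [np.iinfo(np.int64).max]])
            which = np.searchsorted(edges, self.exp_onsets, side="right") - 1
            # one leading exp onset is tolerated: a breath truncated by the
            # record start has its inspiratory onset before sample 0
            if np.sum(which < 0) > 1:
                raise DataError("multiple expiratory onsets precede the first inspiratory onset")
            inside = which >= 0
            if np.any(self.exp_onsets[inside] == edges[which[inside]]):
                raise DataError("expiratory onset coincides with an inspiratory onset")
            counts = np.bincount(which[inside], minlength=len(self.insp_onsets))
            if np.any(counts > 1):
                raise DataError("more than one expiratory onset in a breath interval")

    def coarse_types(self) -> np.ndarray | None:
        if self.breath_types is None:
            return None
        return np.array([_FINE_TO_COARSE.get(str(t), "normal") for t in self.breath_types], dtype=object)

    def exp_for_breath(self) -> np.ndarray:
        """Expiratory onset index per breath (-1 where absent)."""
        out = np.full(len(self.insp_onsets), -1, dtype=np.int64)
        if not self.insp_onsets.size:
            return out
        edges = np.concatenate([self.insp_onsets, [np.iinfo(np.int64).max]])
        which = np.searchsorted(edges, self.exp_onsets, side="right") - 1
        for k, e in zip(which, self.exp_onsets):
            if 0 <= k < len(out) and out[k] < 0:  # first exp onset of the breath
                out[k] = e
        return out


@dataclass
class WaveformRecord:
    """A patient's two-channel 50 Hz pressure/flow series with optional labels."""

    patient_id: str
    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    sample_rate: float = 50.0
    annotation: OnsetAnnotation | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=np.float64)
        self.pressure = np.asarray(self.pressure, dtype=np.float64)
        self.flow = np.asarray(self.flow, dtype=np.float64)
        if not (len(self.time) == len(self.pressure) == len(self.flow)):
            raise DataError("time, pressure, flow must have identical length")
        if len(self.time) < 1:
            raise DataError("record must contain at least one sample")
        if self.sample_rate <= 0:
            raise DataError("sample_rate must be positive")
        step = 1.0 / self.sample_rate
        bad = np.nonzero(np.abs(np.diff(self.time) - step) > 1e-9)[0]
        if bad.size:
            raise DataError(
                f"non-uniform time step at index {int(bad[0]) + 1}: "
                f"expected {step} s within 1e-9"
            )

    def __len__(self) -> int:
        return len(self.time)

    def with_annotation(self, annotation: OnsetAnnotation | None) -> "WaveformRecord":
        return replace(self, annotation=annotation)


@dataclass
class WindowBatch:
    """Normalized 352-sample input windows with central 176-sample targets.

    ``inputs``: (N, input_len, 2) z-scored per window and channel;
    ``targets``: (N, output_len, 2) binary, channel 0 = inspiratory onsets,
    channel 1 = expiratory onsets; ``None`` for inference-only batches.
    ``window_starts`` gives the record sample index of each output span start.
    """

    inputs: np.ndarray
    targets: np.ndarray | None
    window_starts: np.ndarray
    record_ids: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.inputs)

    @staticmethod
    def concatenate(batches: list["WindowBatch"]) -> "WindowBatch":
        has_targets = all(b.targets is not None for b in batches)
        return WindowBatch(
            inputs=np.concatenate([b.inputs for b in batches]),
            targets=np.concatenate([b.targets for b in batches]) if has_targets else None,
            window_starts=np.concatenate([b.window_starts for b in batches]),
            record_ids=[r for b in batches for r in b.record_ids],
        )


# ---------------------------------------------------------------------------
# file I/O (CSV dialect: time,pressure,flow[,insp_onset,exp_onset,breath_type])


def read_record(path, sample_rate: float | None = None, patient_id: str | None = None) -> WaveformRecord:
    """Read a waveform CSV into a validated :class:`WaveformRecord`.

    The time column must step uniformly by ``1/sample_rate``; when
    ``sample_rate`` is None it is inferred from the median time step.  Label
    columns (``insp_onset``/``exp_onset`` 0/1 flags per sample and an optional
    per-breath ``breath_type`` string at inspiratory-onset rows) are parsed
    into an :class:`OnsetAnnotation` when present.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time", "pressure", "flow"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column '{col}'")
    time = df["time"].to_numpy(dtype=np.float64)
    if sample_rate is None:
        if len(time) < 2:
            raise FormatError(f"{path.name}: cannot infer sample rate from one row")
        sample_rate = 1.0 / float(np.median(np.diff(time)))
        sample_rate = float(np.round(sample_rate, 6))
    annotation = None
    if "insp_onset" in df.columns and "exp_onset" in df.columns:
        insp = np.nonzero(df["insp_onset"].to_numpy() > 0)[0]
        exp = np.nonzero(df["exp_onset"].to_numpy() > 0)[0]
        btypes = None
        if "breath_type" in df.columns:
            raw = df["breath_type"].astype("string")
            btypes = np.array([str(raw.iloc[i]) for i in insp], dtype=object)
        annotation = OnsetAnnotation(insp, exp, btypes)
    record = WaveformRecord(
        patient_id=patient_id or path.stem,
        time=time,
        pressure=df["pressure"].to_numpy(dtype=np.float64),
        flow=df["flow"].to_numpy(dtype=np.float64),
        sample_rate=sample_rate,
        annotation=annotation,
    )
    if annotation is not None:
        annotation.validate(len(record))
    return record


def write_record(record: WaveformRecord, path) -> None:
    """Write a record (and its annotation, if any) to the CSV dialect."""
    n = len(record)
    data = {"time": record.time, "pressure": record.pressure, "flow": record.flow}
    ann = record.annotation
    if ann is not None:
        insp = np.zeros(n, dtype=np.int64)
        insp[ann.insp_onsets] = 1
        exp = np.zeros(n, dtype=np.int64)
        exp[ann.exp_onsets] = 1
        data["insp_onset"] = insp
        data["exp_onset"] = exp
        if ann.breath_types is not None:
            bt = np.full(n, "", dtype=object)
            bt[ann.insp_onsets] = ann.breath_types
            data["breath_type"] = bt
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# windowing


def window_samples(duration: float, sample_rate: float) -> int:
    """Convert a duration to a sample count (7.04 s at 50 Hz -> 352)."""
    if duration <= 0 or sample_rate <= 0:
        raise ConfigurationError("duration and sample_rate must be positive")
    product = duration * sample_rate
    if abs(product - round(product)) > 1e-9:
        raise ConfigurationError(
            f"duration {duration} s is not an integer number of samples at {sample_rate} Hz"
        )
    return int(round(product))


def normalize_window(window: np.ndarray) -> np.ndarray:
    """Z-score each channel within the window (population std).

    A constant channel maps to all zeros rather than dividing by zero.
    """
    window = np.asarray(window, dtype=np.float64)
    mean = window.mean(axis=0, keepdims=True)
    std = window.std(axis=0, keepdims=True)
    out = np.zeros_like(window)
    ok = std[0] > 0
    out[:, ok] = (window[:, ok] - mean[:, ok]) / std[:, ok]
    return out


def make_windows(
    record: WaveformRecord,
    input_len: int = 352,
    output_len: int = 176,
    step: int = 176,
) -> WindowBatch:
    """Tile a record into normalized input windows and central target spans.

    Output spans cover ``[0, K*output_len)`` with ``K = ceil(len/output_len)``
    at the default step, each sample exactly once.  Raw signals are
    reflection-padded so edge windows have full input context (and so the last
    span may extend past the record end); normalization happens per window
    after padding.  Targets carry 1 exactly at annotated onset samples.
    """
    if input_len % 2 or output_len > input_len or step < 1:
        raise ConfigurationError("need even input_len, output_len <= input_len, step >= 1")
    n = len(record)
    if n < output_len:
        raise DataError(f"record of {n} samples is shorter than output_len={output_len}")
    margin = (input_len - output_len) // 2
    starts = np.arange(0, n, step)
    starts = starts[starts < n]  # span starts in record coordinates
    if step == output_len:  # exact tiling contract
        k = int(np.ceil(n / output_len))
        starts = np.arange(k) * output_len
    end_needed = int(starts[-1] + output_len)
    pad_right = margin + max(0, end_needed - n)
    raw = np.stack([record.pressure, record.flow], axis=1)
    padded = np.pad(raw, ((margin, pad_right), (0, 0)), mode="reflect")

    inputs = np.empty((len(starts), input_len, 2), dtype=np.float32)
    for i, s in enumerate(starts):
        inputs[i] = normalize_window(padded[s : s + input_len])

    targets = None
    ann = record.annotation
    if ann is not None:
        targets = np.zeros((len(starts), output_len, 2), dtype=np.float32)
        for ch, onsets in enumerate((ann.insp_onsets, ann.exp_onsets)):
            for idx in onsets:
                w = int(idx // step) if step == output_len else None
                if w is None:
                    continue
                if w < len(starts):
                    targets[w, idx - starts[w], ch] = 1.0
        if step != output_len:
            targets = np.zeros((len(starts), output_len, 2), dtype=np.float32)
            for ch, onsets in enumerate((ann.insp_onsets, ann.exp_onsets)):
                for idx in onsets:
                    for w, s in enumerate(starts):
                        if s <= idx < s + output_len:
                            targets[w, idx - s, ch] = 1.0
    return WindowBatch(
        inputs=inputs,
        targets=targets,
        window_starts=starts.astype(np.int64),
        record_ids=[record.patient_id] * len(starts),
    )


def check_disjoint_provenance(batch_a: WindowBatch, batch_b: WindowBatch) -> None:
    """Raise :class:`LeakageError` if two batches share any record."""
    overlap = set(batch_a.record_ids) & set(batch_b.record_ids)
    if overlap:
        raise LeakageError(f"record provenance overlaps between splits: {sorted(overlap)}")
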