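"""Synthetic two-channel ventilator waveforms with planted ground truth.

The generator emulates the structure of real volume/pressure-control
recordings from an ICU ventilator at 50 Hz: trains of breaths with
inspiratory durations around 0.8-0.9 s, expiratory durations 1.1-2.8 s, peak
flows 50-85 L/min, peak pressures 20-35 cm H2O and tidal volumes roughly
280-510 mL, plus a configurable prevalence of the two asynchrony patterns the
package quantifies:

* ``double_trigger`` — a truncated expiration (Te <= 0.3 s) with almost no
  exhaled volume, immediately followed by a second insufflation;
* ``stacked`` — a normal-length expiration that exhales well under the
  inhaled volume (TVe/TVi < 0.9), so volume accumulates;
* ``artifact`` — an otherwise normal breath overlaid with a short cough-like
  high-frequency flow burst during expiration.

Inspiratory flow is square or linearly decelerating; expiratory flow is a
single exponential decay (time constant Te/3) rescaled so the exhaled volume
equals ``exhale_fraction`` x the inhaled volume.  Noise (white Gaussian per
channel plus slow sinusoidal baseline wander) is added only after the exact
onset indices and breath labels are recorded, so the annotation is ground
truth by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ConfigurationError, OnsetAnnotation, WaveformRecord

__all__ = ["BreathSpec", "SimConfig", "synth_breath", "synth_record", "simulate_cohort"]


@dataclass
class BreathSpec:
    """Parameters of one synthetic breath."""

    ti: float  # inspiratory duration, s
    te: float  # expiratory duration, s
    peak_flow: float  # L/min
    peep: float = 5.0  # cm H2O
    peak_pressure: float = 25.0  # cm H2O
    insp_shape: str = "decelerating"  # square | decelerating
    exhale_fraction: float = 1.0  # fraction of inhaled volume exhaled
    btype: str = "normal"  # normal | double_trigger | stacked | artifact

    def __post_init__(self):
        if self.ti <= 0 or self.te <= 0:
            raise ConfigurationError("ti and te must be positive")
        if not (0 < self.exhale_fraction <= 1):
            raise ConfigurationError("exhale_fraction must lie in (0, 1]")
        if self.peak_flow <= 0:
            raise ConfigurationError("peak_flow must be positive")
        if self.insp_shape not in ("square", "decelerating"):
            raise ConfigurationError(f"unknown insp_shape '{self.insp_shape}'")


@dataclass
class SimConfig:
    """Cohort-level generator configuration.

    Defaults follow the real cohort where a statistic is published: 294
    breaths per patient, 28% asynchrony prevalence, ~6% artifact breaths.
    Noise levels are a package choice representing a moderately noisy
    circuit: 1 L/min white flow noise and 0.5 cm H2O pressure noise.  Slow
    baseline wander is kept small (0.2 per channel): ventilator flow sensors
    are auto-zeroed, and a slow flow offset integrates into tidal-volume
    error, which would make the volumetric asynchrony definitions ill-posed
    regardless of segmentation quality (their decision margins are 0.05 in
    TVe/TVi; a 0.2 L/min drift perturbs measured ratios by < 0.04).
    """

    n_patients: int = 10
    breaths_per_patient: int = 294
    asynchrony_fraction: float = 0.28
    artifact_fraction: float = 0.06
    dt_within_asynchrony: float = 0.5  # share of asynchronous breaths that are double triggers
    noise_sd_flow: float = 1.0  # L/min
    noise_sd_pressure: float = 0.5  # cm H2O
    baseline_wander_amplitude: float = 0.2
    sample_rate: float = 50.0
    seed: int = 0

    def __post_init__(self):
        for name in ("asynchrony_fraction", "artifact_fraction", "dt_within_asynchrony"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.n_patients < 1 or self.breaths_per_patient < 1:
            raise ConfigurationError("counts must be >= 1")


def synth_breath(spec: BreathSpec, sample_rate: float = 50.0):
    """Generate one noise-free breath.

    Returns ``(flow, pressure, (insp_offset, exp_offset))`` where flow is in
    L/min, pressure in cm H2O, and the onsets are sample offsets into the
    segment (inspiratory onset at 0, expiratory at ``round(ti*rate)``).
    """
    n_i = int(round(spec.ti * sample_rate))
    n_e = int(round(spec.te * sample_rate))
    if n_i < 2 or n_e < 2:
        raise ConfigurationError("ti and te must each span at least 2 samples")
    dt = 1.0 / sample_rate

    if spec.insp_shape == "square":
        flow_i = np.full(n_i, spec.peak_flow)
    else:  # linear deceleration from peak to zero at end of inspiration
        flow_i = spec.peak_flow * (1.0 - np.arange(n_i) / n_i)
    tvi = np.trapezoid(flow_i, dx=dt)  # L/min * s

    tau = spec.te / 3.0
    shape = -np.exp(-np.arange(n_e) * dt / tau)
    area = np.trapezoid(-shape, dx=dt)
    scale = spec.exhale_fraction * tvi / area
    flow_e = shape * scale

    flow = np.concatenate([flow_i, flow_e])

    rise = 1.0 - np.exp(-np.arange(n_i) * dt / (spec.ti / 4.0))
    pressure_i = spec.peep + (spec.peak_pressure - spec.peep) * rise
    p_end = pressure_i[-1]
    pressure_e = spec.peep + (p_end - spec.peep) * np.exp(-np.arange(n_e) * dt / (spec.te / 5.0))
    pressure = np.concatenate([pressure_i, pressure_e])
    return flow, pressure, (0, n_i)


def _draw_spec(rng: np.random.Generator, btype: str) -> BreathSpec:
    """Draw breath parameters for a given planted type.

    Ranges are calibrated so that cohort medians land inside the published
    interquartile ranges, and so that asynchronous breaths keep a margin of
    at least 0.05 from every decision boundary of the definition-based
    classifiers (Te boundaries at 0.3 s, TVe/TVi boundaries at 0.25/0.9).
    """
    ti = rng.uniform(0.75, 0.95)
    peak_flow = rng.uniform(50.0, 85.0)
    peak_pressure = rng.uniform(20.0, 35.0)
    peep = rng.uniform(4.0, 6.0)
    if btype == "double_trigger":
        te = rng.uniform(0.12, 0.25)
        ef = rng.uniform(0.05, 0.20)
    elif btype == "stacked":
        te = rng.uniform(0.5, 1.6)
        ef = rng.uniform(0.40, 0.85)
    else:  # normal or artifact carrier breath
        te = rng.uniform(1.1, 2.8)
        ef = rng.uniform(0.97, 1.0)
    return BreathSpec(
        ti=ti,
        te=te,
        peak_flow=peak_flow,
        peep=peep,
        peak_pressure=peak_pressure,
        insp_shape="decelerating",
        exhale_fraction=ef,
        btype=btype,
    )


def _add_artifact(rng: np.random.Generator, flow: np.ndarray, n_i: int, sample_rate: float) -> None:
    """Overlay a short cough-like burst during expiration (in place)."""
    n = len(flow)
    burst_len = min(int(0.3 * sample_rate), n - n_i - 2)
    if burst_len < 4:
        return
    start = n_i + 1 + int(rng.integers(0, max(1, n - n_i - burst_len - 1)))
    t = np.arange(burst_len) / sample_rate
    freq = rng.uniform(8.0, 12.0)
    envelope = np.sin(np.pi * np.arange(burst_len) / burst_len)
    flow[start : start + burst_len] += 20.0 * envelope * np.sin(2 * np.pi * freq * t)


def _patient_record(rng: np.random.Generator, config: SimConfig, patient_id: str):
    specs: list[BreathSpec] = []
    for _ in range(config.breaths_per_patient):
        u = rng.random()
        if u < config.artifact_fraction:
            btype = "artifact"
        elif u < config.artifact_fraction + config.asynchrony_fraction:
            btype = (
                "double_trigger"
                if rng.random() < config.dt_within_asynchrony
                else "stacked"
            )
        else:
            btype = "normal"
        specs.append(_draw_spec(rng, btype))

    # recordings start mid-expiration: a 1 s strictly-negative run-in so the
    # first inspiratory onset is a genuine flow crossing, as in real captures
    lead_n = int(round(1.0 * config.sample_rate))
    lead_t = np.arange(lead_n) / config.sample_rate
    flows = [-3.0 * np.exp(-lead_t / 0.3) - 1e-3]
    pressures = [np.full(lead_n, specs[0].peep)]
    insp_onsets, exp_onsets, btypes = [], [], []
    artifact_slots = []
    offset = lead_n
    for spec in specs:
        flow, pressure, (i_on, e_on) = synth_breath(spec, config.sample_rate)
        insp_onsets.append(offset + i_on)
        exp_onsets.append(offset + e_on)
        btypes.append(spec.btype)
        if spec.btype == "artifact":
            artifact_slots.append((offset, e_on, len(flow)))
        flows.append(flow)
        pressures.append(pressure)
        offset += len(flow)

    flow = np.concatenate(flows)
    pressure = np.concatenate(pressures)

    # ground truth is frozen; noise and artifacts are added afterwards
    for start, n_i, seg_len in artifact_slots:
        seg = flow[start : start + seg_len]
        _add_artifact(rng, seg, n_i, config.sample_rate)

    n = len(flow)
    t = np.arange(n) / config.sample_rate
    if config.noise_sd_flow > 0:
        flow = flow + rng.normal(0.0, config.noise_sd_flow, n)
    if config.noise_sd_pressure > 0:
        pressure = pressure + rng.normal(0.0, config.noise_sd_pressure, n)
    if config.baseline_wander_amplitude > 0:
        for sig in (flow, pressure):
            phase = rng.uniform(0, 2 * np.pi)
            freq = rng.uniform(0.02, 0.08)
            sig += config.baseline_wander_amplitude * np.sin(2 * np.pi * freq * t + phase)

    annotation = OnsetAnnotation(
        np.asarray(insp_onsets), np.asarray(exp_onsets), np.asarray(btypes, dtype=object)
    )
    record = WaveformRecord(
        patient_id=patient_id,
        time=t,
        pressure=pressure,
        flow=flow,
        sample_rate=config.sample_rate,
        annotation=annotation,
    )
    manifest = pd.DataFrame(
        {
            "patient_id": patient_id,
            "insp_onset": insp_onsets,
            "exp_onset": exp_onsets,
            "breath_type": btypes,
            "ti": [s.ti for s in specs],
            "te": [s.te for s in specs],
            "peak_flow": [s.peak_flow for s in specs],
            "exhale_fraction": [s.exhale_fraction for s in specs],
        }
    )
    return record, manifest


def synth_record(config: SimConfig) -> list[WaveformRecord]:
    """Generate the cohort of synthetic patient records (reproducible by seed)."""
    return simulate_cohort(config)[0]


def simulate_cohort(config: SimConfig):
    """Generate records plus a manifest DataFrame of the planted truth."""
    records, manifests = [], []
    for p in range(config.n_patients):
        # fixed per-patient substream: reruns and subsets are reproducible
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, p]))
        record, manifest = _patient_record(rng, config, f"sim{p:03d}")
        records.append(record)
        manifests.append(manifest)
    return records, pd.concat(manifests, ignore_index=True)
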