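"""Shared fixtures.

The session-scoped fixtures at the bottom carry the one expensive artifact of
the suite — a U-Net trained on a ~2,000-breath synthetic cohort with 3 L/min
flow noise — shared by the end-to-end acceptance tests.
"""

import numpy as np
import pytest

from ventseg.core import OnsetAnnotation, WaveformRecord
from ventseg.simulate import SimConfig, simulate_cohort
from ventseg.unet import UNetSegmenter


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(flow, pressure=None, sample_rate=50.0, patient_id="t", annotation=None):
    flow = np.asarray(flow, dtype=float)
    if pressure is None:
        pressure = np.zeros_like(flow)
    return WaveformRecord(
        patient_id=patient_id,
        time=np.arange(len(flow)) / sample_rate,
        pressure=np.asarray(pressure, dtype=float),
        flow=flow,
        sample_rate=sample_rate,
        annotation=annotation,
    )


@pytest.fixture
def simple_record():
    """One square breath: 1 s inspiration at 30 L/min, 2 s expiration."""
    flow = np.concatenate([np.full(50, 30.0), np.full(100, -10.0)])
    ann = OnsetAnnotation([0], [50], ["normal"])
    return make_record(flow, annotation=ann)


NOISEFREE = dict(
    asynchrony_fraction=0.0,
    artifact_fraction=0.0,
    noise_sd_flow=0.0,
    noise_sd_pressure=0.0,
    baseline_wander_amplitude=0.0,
)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """200 normal breaths, no noise: both heuristics must be near-perfect."""
    return simulate_cohort(SimConfig(n_patients=2, breaths_per_patient=100, seed=11, **NOISEFREE))


# --- the trained-model world (acceptance criteria 6-8) ----------------------

#: ~2,000 breaths from 10 synthetic patients at 3 L/min flow noise — the
#: noisy regime in which the learned model must beat the heuristics
ACCEPTANCE_SIM = SimConfig(
    n_patients=10,
    breaths_per_patient=200,
    asynchrony_fraction=0.28,
    artifact_fraction=0.03,
    noise_sd_flow=3.0,
    noise_sd_pressure=0.5,
    baseline_wander_amplitude=0.2,
    seed=7,
)

#: CPU-sized network; the published filter counts are not stated, and the
#: acceptance protocol explicitly scales the model down for desk hardware
ACCEPTANCE_SEGMENTER = dict(
    depth=4, base_filters=8, convs_per_block=1, max_epochs=30, patience=10, seed=7
)


@pytest.fixture(scope="session")
def acceptance_world():
    records, manifest = simulate_cohort(ACCEPTANCE_SIM)
    return {
        "train": records[:8],
        "val": records[8:9],
        "test": records[9:],
        "manifest": manifest,
    }


@pytest.fixture(scope="session")
def trained_segmenter(acceptance_world):
    seg = UNetSegmenter(**ACCEPTANCE_SEGMENTER)
    seg.fit(acceptance_world["train"], val_records=acceptance_world["val"])
    return seg
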