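"""Shared fixtures: bead calibration, a reference synthetic sample and a
pipeline configuration scaled to test-size acquisitions."""

import numpy as np
import pytest

import sputumflow as sf
from sputumflow.pipeline import PipelineConfig


@pytest.fixture(scope="session")
def bead_gate():
    beads = sf.generate_bead_run([5.0, 20.0, 30.0], np.random.default_rng(0))
    return sf.size_gate_from_beads(beads, [5.0, 20.0, 30.0])


@pytest.fixture(scope="session")
def scaled_config():
    """Pipeline thresholds relaxed to match test-size control acquisitions."""
    return PipelineConfig(min_control_events=200, min_strata_events=300)


@pytest.fixture(scope="session")
def hr_sample():
    """One high-risk sample at moderate event count, with truth labels."""
    config = sf.build_sample_config(
        sf.default_sample_params("high_risk"), "HR_fixture",
        n_events=20_000, control_n_events=10_000, seed=42,
    )
    tubes = sf.generate_sample(config)
    controls = sf.generate_controls(config)
    return config, tubes, controls


@pytest.fixture(scope="session")
def hr_result(hr_sample, bead_gate, scaled_config):
    _, tubes, controls = hr_sample
    return sf.run_sample(tubes, controls, bead_gate, scaled_config)


def run_cohort_panel(cohort_config, bead_gate, pipeline_config):
    """Generate a cohort, gate every sample and run the comparison panel."""
    samples = sf.generate_cohort(cohort_config)
    results, meta = [], []
    for s in samples:
        results.append(sf.run_sample(s.tubes, s.controls, bead_gate, pipeline_config))
        meta.append({"group": s.group, "smoking": s.smoking, "stage": s.stage})
    return sf.run_comparison_panel(results, meta)
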