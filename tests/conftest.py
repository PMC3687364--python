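"""Shared fixtures: one default synthetic dataset reused across the suite."""

import numpy as np
import pytest

from nascentx.pipeline import run_tss_stage
from nascentx.signal import compute_mappability
from nascentx.simulate import SimConfig, generate_genome, pileups_for_condition
from nascentx.tss import TssCallerConfig


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition synthetic dataset: genome, annotations, truth, mappability."""
    cfg = SimConfig(seed=1)
    genome, annotations, truth = generate_genome(cfg)
    mapp = compute_mappability(genome)
    return cfg, genome, annotations, truth, mapp


@pytest.fixture(scope="session")
def control_stage(default_sim):
    cfg, genome, annotations, truth, mapp = default_sim
    tracks = pileups_for_condition(annotations, truth, cfg, "control", seed=11)
    return run_tss_stage(
        tracks["groseq"], tracks["tap_plus"], tracks["tap_minus"],
        annotations, mapp, TssCallerConfig(), stage_label="embryo",
    )


@pytest.fixture(scope="session")
def mutant_stage(default_sim):
    cfg, genome, annotations, truth, mapp = default_sim
    tracks = pileups_for_condition(annotations, truth, cfg, "mutant", seed=12)
    return run_tss_stage(
        tracks["groseq"], tracks["tap_plus"], tracks["tap_minus"],
        annotations, mapp, TssCallerConfig(), stage_label="sdc2_embryo",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
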