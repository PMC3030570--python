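"""Shared fixtures: one synthetic genome and one full pipeline run per
session, reused by the module and acceptance suites."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from fbxscape.pipeline import PipelineConfig, run_pipeline
from fbxscape.simulate import SimulationConfig, generate_family_genome


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    """The default study conditions: 30 coding + 20 pseudogene loci."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def sim_data(sim_config):
    """(genome, references, truth) for the default synthetic genome."""
    return generate_family_genome(sim_config)


@pytest.fixture(scope="session")
def pipeline_run():
    """One full pipeline execution on the default synthetic genome."""
    cfg = PipelineConfig(seed=1)
    cfg.simulation.seed = 1
    report, artifacts = run_pipeline(cfg)
    return report, artifacts


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
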