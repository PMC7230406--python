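"""Shared fixtures: one synthetic dataset and one full pipeline run per session."""

from __future__ import annotations

import pytest

from lncscreen.pipeline import PipelineConfig, run_all
from lncscreen.synthetic_data import SynthConfig, generate_all
from lncscreen.thermo import load_params


@pytest.fixture(scope="session")
def energy_params():
    return load_params()


@pytest.fixture(scope="session")
def dataset():
    """The default synthetic dataset (seed 7), generated once per session."""
    return generate_all(SynthConfig())


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One complete pipeline run on the default synthetic configuration."""
    run_dir = tmp_path_factory.mktemp("pipeline") / "run"
    config = PipelineConfig(run_dir=str(run_dir), seed=7)
    run_all(config)
    return run_dir
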