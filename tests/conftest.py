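"""Shared fixtures: a session-scoped noiseless synthetic system and its
full pipeline run, reused by the comparative/pipeline/acceptance tests."""

from __future__ import annotations

import pytest

from rhizocomp.pipeline import PipelineConfig, run_pipeline
from rhizocomp.synthdata import SyntheticConfig, generate


@pytest.fixture(scope="session")
def noiseless_dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("synth_noiseless")
    dataset = generate(SyntheticConfig.noiseless(), seed=42, outdir=outdir)
    return dataset, outdir


@pytest.fixture(scope="session")
def noiseless_run(noiseless_dataset, tmp_path_factory):
    dataset, synth_dir = noiseless_dataset
    run_dir = tmp_path_factory.mktemp("run_noiseless")
    config = PipelineConfig.from_yaml(synth_dir / "pipeline.yaml")
    result = run_pipeline(config, run_dir)
    return dataset, config, result
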