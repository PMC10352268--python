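import pytest

from lowfield_relax import PipelineConfig, build_default_agents, run_pipeline


@pytest.fixture(scope="session")
def agents():
    """Default agent specs keyed by name."""
    return {a.name: a for a in build_default_agents()}


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default pipeline run (all 7 agents, both fields, SNR 50),
    shared by the end-to-end tests."""
    out = tmp_path_factory.mktemp("pipeline_default")
    cfg = PipelineConfig(seed=1, out_dir=str(out))
    manifest, results = run_pipeline(cfg)
    return cfg, manifest, results
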