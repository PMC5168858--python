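import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_synthetic(tmp_path_factory):
    """One small two-strain synthetic run (noise=0), shared across tests."""
    from memfunnel.pipeline import run_synthetic
    from memfunnel.simulate import GeneratorConfig

    workdir = tmp_path_factory.mktemp("synth")
    cfg = GeneratorConfig(
        n_transcripts=150, strain_names=("alpha", "beta"), seed=101
    )
    result, truth = run_synthetic(cfg, workdir)
    return cfg, workdir, result, truth
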