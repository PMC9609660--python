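import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def zero_noise_paths(tmp_path_factory):
    """Synthetic experiment with every noise source disabled."""
    from rumenbatch.pipeline import simulate_experiment

    out = tmp_path_factory.mktemp("zero_noise")
    return simulate_experiment(out, seed=0, noise_scale=0.0)


@pytest.fixture(scope="session")
def zero_noise_results(zero_noise_paths, tmp_path_factory):
    """Full pipeline output on the zero-noise experiment."""
    from rumenbatch.pipeline import PipelineConfig, run_full_pipeline

    out = tmp_path_factory.mktemp("zero_noise_out")
    cfg = PipelineConfig(
        gas_path=str(zero_noise_paths["gas"]),
        chemistry_path=str(zero_noise_paths["chemistry"]),
        amino_acids_path=str(zero_noise_paths["amino_acids"]),
        qpcr_path=str(zero_noise_paths["qpcr"]),
        otu_path=str(zero_noise_paths["otu"]),
        out_dir=str(out),
        n_permutations=99,
        seed=1,
    )
    return run_full_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
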