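import pytest

from mztdecay.simulate import SimConfig, generate_expression


@pytest.fixture(scope="session")
def noiseless_sim():
    """Small zero-noise simulation: every planted signal must be exact."""
    config = SimConfig(genes_per_archetype=25, replicates=2,
                       noise_sd_log2=0.0, ct_noise_sd=0.0, seed=11)
    matrix, truth = generate_expression(config)
    return config, matrix, truth


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-noise simulation at reduced size for distributional checks."""
    config = SimConfig(genes_per_archetype=50, replicates=3,
                       noise_sd_log2=0.2, seed=7)
    matrix, truth = generate_expression(config)
    return config, matrix, truth
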