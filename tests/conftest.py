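import numpy as np
import pytest

from ethome.io import StimulusEpoch, StimulusProtocol
from ethome.synth import NoiseParams, PopulationConfig, simulate_population


@pytest.fixture(scope="session")
def short_protocol() -> StimulusProtocol:
    """Compressed assay for fast tests: 10 s baseline, 10 s air puff."""
    return StimulusProtocol(
        epochs=[StimulusEpoch(modality="air_puff", onset=10.0, duration=10.0, intensity=4.0)]
    )


@pytest.fixture(scope="session")
def small_population(short_protocol):
    """Six noiseless larvae on the compressed assay, with ground truth."""
    cfg = PopulationConfig(
        n_larvae=6, total_s=25.0, noise=NoiseParams(), dropout=0.0, seed=11
    )
    return simulate_population(cfg, short_protocol)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
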