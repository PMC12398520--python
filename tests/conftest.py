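import numpy as np
import pytest

from transdyn import SimConfig, cds_sequences, simulate_footprints


@pytest.fixture(scope="session")
def footprint_world():
    """A moderately deep simulated footprint library shared across tests.

    30 transcripts of 300-600 codons, 60k reads, uniform codon dwell
    weights, known P-site offsets.
    """
    cfg = SimConfig(
        seed=11,
        n_footprints=60_000,
        n_transcripts=30,
        cds_length_range=(300, 600),
    )
    transcripts, models, footprints = simulate_footprints(cfg)
    return cfg, transcripts, models, footprints


@pytest.fixture(scope="session")
def footprint_cds(footprint_world):
    cfg, transcripts, models, _ = footprint_world
    return cds_sequences(transcripts, models)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
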