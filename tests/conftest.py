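import numpy as np
import pytest

from brugadanet.backbone import BackboneConfig
from brugadanet.containers import BeatDataset
from brugadanet.preprocess import records_to_beats
from brugadanet.synth import CohortSpec, generate_cohort

#: small but non-trivial backbone used throughout the unit tests
SMALL_BACKBONE = BackboneConfig(n_dense_blocks=4, layers_per_block=2,
                                growth_rate=8, kernel_size=5,
                                trunk_channels=12, embedding_dim=16,
                                min_pool_length=20)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Materialised 28-patient cohort shared across tests (read-only)."""
    spec = CohortSpec(class_counts={"normal": 12, "rbbb": 8,
                                    "brugada_type1": 4, "brugada_type2": 4},
                      record_duration_s=6.0, seed=1234)
    manifest, records = generate_cohort(spec)
    return spec, manifest, records


@pytest.fixture(scope="session")
def tiny_beats(tiny_cohort):
    _, _, records = tiny_cohort
    return BeatDataset.from_beat_tensors(
        records_to_beats(records, use_true_peaks=True))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(99)
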