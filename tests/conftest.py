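import numpy as np
import pytest

from careseq.cohort import default_config, generate_cohort
from careseq.dissimilarity import distance_matrix
from careseq.sequences import (
    IndividualRecord,
    WaveObservation,
    build_panel,
    fill_intermittent,
)


def make_record(rec_id, triples, first_year=2015, demographics=None):
    """Record from a list of (t, c, m) triples; None entries are missing waves."""
    waves = tuple(
        WaveObservation() if t is None else WaveObservation(*t) for t in triples
    )
    return IndividualRecord(rec_id, first_year, waves, demographics or {})


@pytest.fixture(scope="session")
def cohort4():
    """Planted 4-archetype cohort at moderate size (used across modules)."""
    return generate_cohort(default_config(n=200, seed=7, include_heterogeneous=False))


@pytest.fixture(scope="session")
def panel4(cohort4):
    return build_panel([fill_intermittent(r) for r in cohort4.records])


@pytest.fixture(scope="session")
def truth4(cohort4):
    return {r.id: label for r, label in zip(cohort4.records, cohort4.true_labels)}


@pytest.fixture(scope="session")
def D4(panel4):
    return distance_matrix(panel4)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
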