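import numpy as np
import pytest

from lea_profiler.motif_engine import default_registry
from lea_profiler.seq_io import ProteinRecord, ProteomeSet


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)


@pytest.fixture
def random_proteome(rng):
    """50 random synthetic records, lengths 30-200."""
    residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    records = []
    for i in range(50):
        n = int(rng.integers(30, 201))
        seq = "".join(rng.choice(residues, size=n))
        records.append(ProteinRecord(id=f"rand{i:03d}", sequence=seq, source="synthetic"))
    return ProteomeSet(records=records, provenance="random fixture")
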