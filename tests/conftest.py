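import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from genedrug.data_model import write_dataset
from genedrug.synthetic_data import SimulationConfig, fixture_minimal, generate


@pytest.fixture
def minimal_ds():
    return fixture_minimal()


@pytest.fixture
def minimal_corpus_dir(tmp_path, minimal_ds):
    """The minimal corpus written as its four canonical TSVs."""
    out = tmp_path / "corpus"
    write_dataset(minimal_ds, out)
    return out


@pytest.fixture(scope="session")
def small_synthetic():
    """A 60-drug planted corpus, shared read-only across tests."""
    cfg = SimulationConfig(n_genes=120, n_diseases=10, n_drugs=60, seed=11)
    return generate(cfg)
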