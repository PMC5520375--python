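import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helpers

from clockmine.simulate import simulate_proteomes


@pytest.fixture(scope="session")
def planted_proteomes():
    """Ten simulated taxa, five homolog families at 70% identity, 20 decoys each."""
    families = [(f"query_{i + 1}", 70.0, 1) for i in range(5)]
    return simulate_proteomes(n_taxa=10, families=families, n_decoys=20, seed=42)
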