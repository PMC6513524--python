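import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from levikit import FamilySpec, SyntheticGenomeSpec, generate_families, generate_genomes


@pytest.fixture(scope="session")
def family_data():
    """Planted three-family protein set with its truth labels."""
    return generate_families(FamilySpec(seed=42))


@pytest.fixture(scope="session")
def genome_data():
    """Planted genomes with canonical TR hairpins and their truth tables."""
    return generate_genomes(SyntheticGenomeSpec(n_genomes=3, seed=42))
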