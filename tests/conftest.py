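import numpy as np
import pytest

from hdxquant import GroundTruthSystem, StateDefinition, generate_peptide_map

AMINO_ACIDS = list("ACDEFGHIKLMNQRSTVWY")  # proline handled explicitly where needed


def random_sequence(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(AMINO_ACIDS, n))


@pytest.fixture
def small_system():
    """Two-state 60-residue system with a protected core, modest noise."""
    seq = random_sequence(60, seed=42)
    profile = np.zeros(60)
    profile[15:45] = 2.0
    states = [
        StateDefinition("apo", seq, profile.copy()),
        StateDefinition("bound", seq, profile.copy()),
    ]
    return GroundTruthSystem(sequence=seq, states=states)


@pytest.fixture
def small_map(small_system):
    return generate_peptide_map(small_system.sequence, target_length=10, overlap=5)
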