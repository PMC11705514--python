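import numpy as np
import pytest

from trnamod.chem import MonomerRegistry, default_registry, parse_sequence


@pytest.fixture(scope="session")
def registry() -> MonomerRegistry:
    return default_registry()


@pytest.fixture(scope="session")
def mods_by_parent(registry):
    """Non-canonical codes grouped by parent base, for random sequence builds."""
    groups = {"A": [], "C": [], "G": [], "U": []}
    for mono in registry:
        if not mono.is_canonical:
            groups[mono.parent].append(mono.code)
    return groups


@pytest.fixture
def tyr_t1_product():
    """The anticodon-spanning RNase T1 product of Tyr tRNA."""
    return parse_sequence("ACU[manQ]UAGp")


@pytest.fixture
def tyr_cusativin_product():
    return parse_sequence("U[manQ]UAGAUCC>p")


def random_modified_sequence(rng: np.random.Generator, length: int, mods_by_parent,
                             mod_prob: float = 0.25, five="OH", three="OH"):
    """Random sequence over canonicals with modifications swapped in."""
    from trnamod.chem import ModifiedSequence

    residues = []
    for _ in range(length):
        base = str(rng.choice(["A", "C", "G", "U"]))
        if rng.random() < mod_prob and mods_by_parent[base]:
            residues.append(str(rng.choice(mods_by_parent[base])))
        else:
            residues.append(base)
    return ModifiedSequence(tuple(residues), five, three)
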