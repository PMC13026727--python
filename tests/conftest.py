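import numpy as np
import pytest

from famendo import (
    EigenA,
    Individual,
    Pedigree,
    kinship_from_pedigree,
    simulate_pedigree,
)


def trio() -> Pedigree:
    return Pedigree(
        [
            Individual("dad", None, None, "male", 0),
            Individual("mom", None, None, "female", 0),
            Individual("kid", "dad", "mom", "male", 1),
        ]
    )


def sib_quartet() -> Pedigree:
    return Pedigree(
        [
            Individual("dad", None, None, "male", 0),
            Individual("mom", None, None, "female", 0),
            Individual("s1", "dad", "mom", "male", 1),
            Individual("s2", "dad", "mom", "female", 1),
        ]
    )


@pytest.fixture(scope="session")
def family_pedigree() -> Pedigree:
    """Mid-sized multigenerational pedigree shared across model tests."""
    return simulate_pedigree(n_families=8, n_generations=3, mean_sibship=4.0, seed=3)


@pytest.fixture(scope="session")
def family_eig(family_pedigree) -> EigenA:
    return EigenA(kinship_from_pedigree(family_pedigree))


@pytest.fixture(scope="session")
def big_pedigree() -> Pedigree:
    """~600-member pedigree matching the simulated-cohort geometry."""
    return simulate_pedigree(n_families=20, n_generations=3, mean_sibship=4.5, seed=11)


@pytest.fixture(scope="session")
def big_eig(big_pedigree) -> EigenA:
    return EigenA(kinship_from_pedigree(big_pedigree))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
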