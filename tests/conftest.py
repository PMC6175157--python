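import numpy as np
import pytest

from sirescan.genotypes import GenotypePanel
from sirescan.pedigree import UNKNOWN, Pedigree
from sirescan.synthetic import (
    SimConfig,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(["S", "D", "O"], np.array([UNKNOWN, UNKNOWN, 0]), np.array([UNKNOWN, UNKNOWN, 1]))


@pytest.fixture
def random_pedigree():
    """Moderately inbred 300-animal pedigree."""
    cfg = SimConfig(n_founders=30, n_generations=4, offspring_per_mating=3, seed=11)
    return simulate_pedigree(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    """Shared small simulated dataset: pedigree, genotypes, phenotypes, truth."""
    cfg = SimConfig(
        n_founders=40,
        n_generations=3,
        offspring_per_mating=2,
        n_snps=300,
        n_chromosomes=3,
        chrom_length_bp=30_000_000,
        records_per_animal_range=(1, 4),
        seed=101,
    )
    ped = simulate_pedigree(cfg)
    panel = simulate_genotypes(ped, cfg)
    phen, truth = simulate_phenotypes(ped, panel, cfg)
    return cfg, ped, panel, phen, truth


def panel_from_counts(n_aa: int, n_ab: int, n_bb: int) -> GenotypePanel:
    """Single-SNP panel realizing the given genotype counts."""
    codes = np.array([0.0] * n_aa + [1.0] * n_ab + [2.0] * n_bb)[:, None]
    ids = [f"a{i}" for i in range(codes.shape[0])]
    return GenotypePanel(ids, ["snp1"], codes, np.array(["1"], dtype=object), np.array([1000]))
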