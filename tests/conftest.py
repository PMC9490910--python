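import numpy as np
import pandas as pd
import pytest

from polyselect import SimConfig, simulate
from polyselect.genotype_io import GenotypeMatrix
from polyselect.kinship import compute_grm
from polyselect.lmm import EigenGRM


def small_config(**overrides) -> SimConfig:
    """A fast, fully specified small-herd configuration for unit tests."""
    base = dict(
        n_founders=80,
        birth_years=tuple(range(2009, 2014)),
        n_offspring_per_year=80,
        n_genotyped_per_year=50,
        prop_female=0.7,
        n_snps=400,
        n_chromosomes=4,
        chrom_length_bp=2_000_000,
        n_qtl_selected=8,
        n_qtl_teat=5,
        n_qtl_pleiotropic=2,
        min_sires=6,
        min_dams=20,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """(genotypes, samples, truth) from a small selection simulation."""
    return simulate(small_config())


@pytest.fixture(scope="session")
def small_drift_sim():
    return simulate(small_config(drift_only=True, seed=23))


@pytest.fixture(scope="session")
def small_grm(small_sim):
    g, _, _ = small_sim
    return compute_grm(g)


@pytest.fixture(scope="session")
def small_eig(small_grm):
    return EigenGRM(small_grm)


def matrix_from(dosages, chrom=None, pos=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a raw dosage array for edge-case tests."""
    d = np.asarray(dosages, dtype=np.int8)
    n, m = d.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    if chrom is None:
        chrom = ["1"] * m
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "id": [f"v{i}" for i in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(d, variants, [f"s{i}" for i in range(n)])
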