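import numpy as np
import pytest

from gainsim import genome_founders as gf
from gainsim import trait_model as tm


@pytest.fixture(scope="session")
def small_map():
    """2 chromosomes × 40 loci, 5 QTN + 8 SNP per chromosome."""
    return gf.build_map(
        n_chromosomes=2,
        chr_lengths_cM=[100.0, 100.0],
        n_loci_total=80,
        n_qtn_per_chr=5,
        n_snp_per_chr=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_founders(small_map):
    return gf.simulate_founders(small_map, n_founders=60, seed=12)


@pytest.fixture(scope="session")
def small_arch(small_map, small_founders):
    return tm.sample_architecture(small_map, small_founders, epistasis_ratio=0.5, seed=13)


@pytest.fixture(scope="session")
def reduced_map():
    """The reduced desk-scale map: 12 chromosomes, 600 loci, 120 QTN/180 SNP."""
    return gf.build_map(
        n_loci_total=600, n_qtn_per_chr=10, n_snp_per_chr=15, seed=21
    )


@pytest.fixture(scope="session")
def reduced_founders(reduced_map):
    return gf.simulate_founders(reduced_map, n_founders=300, seed=22)


def toy_gblup_data(n=60, seed=0, sa2=1.0, saa2=0.5, se2=1.0, m=40):
    """Synthetic phenotypes from the two-kernel model with known components."""
    rng = np.random.default_rng(seed)
    M = rng.integers(0, 3, size=(n, m)).astype(float) - 1.0
    M -= M.mean(axis=0)
    from gainsim.grm_gblup import additive_grm, epistatic_grm

    # blend a little identity: the centered GRM is singular (rows sum to 0),
    # and the Henderson-equation oracle needs invertible kernels
    Ga = 0.95 * additive_grm(M) + 0.05 * np.eye(n)
    _, Gaa = epistatic_grm(Ga)
    La = np.linalg.cholesky(Ga + 1e-8 * np.eye(n))
    Laa = np.linalg.cholesky(Gaa + 1e-8 * np.eye(n))
    y = (
        2.0
        + np.sqrt(sa2) * La @ rng.standard_normal(n)
        + np.sqrt(saa2) * Laa @ rng.standard_normal(n)
        + np.sqrt(se2) * rng.standard_normal(n)
    )
    return y, Ga, Gaa
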