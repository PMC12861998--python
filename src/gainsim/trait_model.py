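"""Quantitative-trait architecture: additive + additive×additive epistasis.

The true genetic value of individual i is the bilinear form

    G_i = Σ_k a_k x_ik + Σ_(k,l) a_kl x_ik x_il

over QTN dosages x_ik coded -1/0/1 and centered at the founder mean per
locus. Epistatic pairs are disjoint random QTN pairs (one interaction per
QTN). The architecture is calibrated on the founder population so that

  * Var(epistatic component) / Var(additive component) equals the requested
    epistasis ratio exactly,
  * founder Var(G) = 1 and founder mean(G) = 0 (responses are therefore in
    founder genetic-standard-deviation units), and
  * the error variance gives the target broad-sense heritability
    H² = Var(G) / (Var(G) + σ_e²) in the founder set.

Phenotypes are Y_i = μ + G_i + ε_i with ε_i ~ N(0, σ_e²); σ_e² is fixed at
calibration and held constant in all later generations and cycles.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .genome_founders import (
    ConfigurationError,
    GeneticMap,
    HaplotypePopulation,
    _as_rng,
)

__all__ = [
    "TraitArchitecture",
    "TraitRealization",
    "sample_architecture",
    "genetic_value",
    "phenotype",
]


@dataclasses.dataclass(frozen=True)
class TraitArchitecture:
    qtn_idx: np.ndarray  # (q,) locus indices of QTNs in map order
    additive_effects: np.ndarray  # (q,) a_k
    pair_idx: np.ndarray  # (P, 2) positions into qtn_idx, disjoint pairs
    pair_effects: np.ndarray  # (P,) a_kl
    dosage_centering: np.ndarray  # (q,) founder mean dosage per QTN
    epistatic_offset: float  # founder mean of the epistatic term (subtracted)
    intercept: float  # μ, trait units
    error_variance: float  # σ_e², trait units²
    epistasis_ratio: float
    target_H2: float

    def __post_init__(self) -> None:
        if self.pair_idx.size:
            flat = self.pair_idx.ravel()
            if len(np.unique(flat)) != len(flat):
                raise ConfigurationError("epistatic pairs must be disjoint")
            if np.any(self.pair_idx[:, 0] == self.pair_idx[:, 1]):
                raise ConfigurationError("an epistatic pair must join distinct QTNs")
        if self.error_variance <= 0:
            raise ConfigurationError("error variance must be positive")

    def serialize(self, path: str) -> None:
        """Plain-text audit tables: per-QTN effects and the pair list."""
        with open(path, "w") as fh:
            fh.write(
                f"# intercept={self.intercept!r} sigma_e2={self.error_variance!r} "
                f"epistasis_ratio={self.epistasis_ratio!r} H2={self.target_H2!r} "
                f"epi_offset={self.epistatic_offset!r}\n"
            )
            fh.write("qtn_locus\tadditive_effect\tdosage_center\n")
            for j, a, c in zip(
                self.qtn_idx, self.additive_effects, self.dosage_centering
            ):
                fh.write(f"{j}\t{float(a)!r}\t{float(c)!r}\n")
            fh.write("pair_k\tpair_l\tpair_effect\n")
            for (k, l), a in zip(self.pair_idx, self.pair_effects):
                fh.write(f"{self.qtn_idx[k]}\t{self.qtn_idx[l]}\t{float(a)!r}\n")


@dataclasses.dataclass
class TraitRealization:
    genetic_values: np.ndarray
    additive_component: np.ndarray
    epistatic_component: np.ndarray
    phenotypes: np.ndarray | None = None


def _scaled_dosage(pop: HaplotypePopulation, arch: TraitArchitecture) -> np.ndarray:
    if pop.gmap.n_loci <= int(arch.qtn_idx.max()):
        raise ConfigurationError("population loci do not align with architecture QTNs")
    return pop.dosage()[:, arch.qtn_idx].astype(np.float64) - arch.dosage_centering


def _components(X: np.ndarray, arch: TraitArchitecture):
    add = X @ arch.additive_effects
    if arch.pair_idx.size:
        epi = (X[:, arch.pair_idx[:, 0]] * X[:, arch.pair_idx[:, 1]]) @ arch.pair_effects
        epi = epi - arch.epistatic_offset
    else:
        epi = np.zeros(len(X))
    return add, epi


def sample_architecture(
    gmap: GeneticMap,
    founders: HaplotypePopulation,
    epistasis_ratio: float = 0.0,
    target_H2: float = 0.63,
    effect_distribution: str = "gaussian",
    intercept: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> TraitArchitecture:
    """Sample and calibrate QTN effects on the founder population.

    ``epistasis_ratio`` is Vaa/Va in the founders (0, 0.5, 1.0 in the study
    design); ``effect_distribution`` is "gaussian" (standard normal, default)
    or "gamma" (shape=1, scale=1 magnitudes with random signs). All effects
    are jointly rescaled after sampling, so the distribution choice affects
    only effect-size skew.
    """
    rng = _as_rng(seed)
    qtn = gmap.qtn_indices
    if qtn.size == 0:
        raise ConfigurationError("map contains no QTNs")
    freqs = founders.allele_frequencies()[qtn]
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ConfigurationError("founders must be polymorphic at every QTN")
    if epistasis_ratio > 0 and qtn.size < 2:
        raise ConfigurationError("epistasis requires at least 2 QTNs")
    if not 0 < target_H2 < 1:
        raise ConfigurationError("target_H2 must be in (0, 1)")

    def draw(size: int) -> np.ndarray:
        if effect_distribution == "gaussian":
            return rng.standard_normal(size)
        if effect_distribution == "gamma":
            return rng.gamma(1.0, 1.0, size) * rng.choice([-1.0, 1.0], size)
        raise ConfigurationError(f"unknown effect distribution {effect_distribution}")

    a = draw(qtn.size)
    centering = founders.dosage()[:, qtn].mean(axis=0)
    X = founders.dosage()[:, qtn].astype(np.float64) - centering
    add = X @ a
    var_add = add.var()
    if var_add <= 0:
        raise ConfigurationError("zero additive variance in founders")

    if epistasis_ratio > 0:
        n_pairs = qtn.size // 2
        perm = rng.permutation(qtn.size)[: 2 * n_pairs]
        pair_idx = perm.reshape(n_pairs, 2)
        b = draw(n_pairs)
        epi_raw = (X[:, pair_idx[:, 0]] * X[:, pair_idx[:, 1]]) @ b
        var_epi = epi_raw.var()
        if var_epi <= 0:
            raise ConfigurationError("degenerate epistatic variance in founders")
        b = b * np.sqrt(epistasis_ratio * var_add / var_epi)
        epi = (X[:, pair_idx[:, 0]] * X[:, pair_idx[:, 1]]) @ b
    else:
        pair_idx = np.empty((0, 2), dtype=np.int64)
        b = np.empty(0)
        epi = np.zeros(founders.n)

    # normalize founder Var(G) to 1; component ratio is scale-invariant
    g = add + epi - epi.mean()
    scale = g.std()
    if scale <= 0:
        raise ConfigurationError("zero total genetic variance in founders")
    a = a / scale
    b = b / scale
    epi_offset = float((epi / scale).mean()) if pair_idx.size else 0.0

    sigma_e2 = (1.0 - target_H2) / target_H2  # Var(G) = 1 after scaling
    return TraitArchitecture(
        qtn_idx=qtn,
        additive_effects=a,
        pair_idx=pair_idx,
        pair_effects=b,
        dosage_centering=centering,
        epistatic_offset=epi_offset,
        intercept=float(intercept),
        error_variance=float(sigma_e2),
        epistasis_ratio=float(epistasis_ratio),
        target_H2=float(target_H2),
    )


def genetic_value(pop: HaplotypePopulation, arch: TraitArchitecture) -> TraitRealization:
    """True genetic values; additive and epistatic parts sum exactly to G."""
    X = _scaled_dosage(pop, arch)
    add, epi = _components(X, arch)
    return TraitRealization(
        genetic_values=add + epi,
        additive_component=add,
        epistatic_component=epi,
    )


def phenotype(
    pop: HaplotypePopulation,
    arch: TraitArchitecture,
    seed: int | np.random.Generator | None = None,
) -> TraitRealization:
    """Y_i = μ + G_i + ε_i with i.i.d. Gaussian noise of variance σ_e²."""
    rng = _as_rng(seed)
    real = genetic_value(pop, arch)
    noise = rng.normal(0.0, np.sqrt(arch.error_variance), size=pop.n)
    real.phenotypes = arch.intercept + real.genetic_values + noise
    return real
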