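"""Genetic map construction and founder-population simulation.

The simulated crop is a diploid, self-pollinated species (rice-like) with 12
chromosome pairs. The genome is represented as a fixed panel of biallelic
segregating sites placed on a centiMorgan map; a subset of sites act as causal
loci (QTNs) and a disjoint subset as genotyping markers (SNPs).

Founders are pure lines: fully homozygous individuals obtained by doubling
haplotypes sampled from a neutral coalescent (msprime). One mutation is
dropped per map locus on a branch of the local genealogy chosen proportional
to branch length, which yields the coalescent allele-frequency spectrum and
genealogical linkage disequilibrium between nearby loci while guaranteeing
polymorphism among the sampled haplotypes.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import msprime
import numpy as np

__all__ = [
    "ROLE_NEUTRAL",
    "ROLE_QTN",
    "ROLE_SNP",
    "ConfigurationError",
    "SimulationError",
    "GeneticMap",
    "HaplotypePopulation",
    "build_map",
    "simulate_founders",
]

ROLE_NEUTRAL = 0
ROLE_QTN = 1
ROLE_SNP = 2

_GENERATION_ORDER = ("founder", "F1", "F2", "F3", "F4", "F5", "F6", "F7", "F8")


class ConfigurationError(ValueError):
    """Raised when requested map/scheme settings are internally inconsistent."""


class SimulationError(RuntimeError):
    """Raised when a stochastic generation step cannot satisfy its contract."""


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclasses.dataclass(frozen=True)
class GeneticMap:
    """Locus positions (cM), chromosome assignment and locus roles.

    Loci are stored chromosome-major; positions are strictly increasing within
    each chromosome. ``role`` holds one of ``ROLE_NEUTRAL``/``ROLE_QTN``/
    ``ROLE_SNP`` per locus — QTN and SNP sets are disjoint by construction.
    """

    chrom: np.ndarray  # (L,) int16, 0-based chromosome index
    pos_cM: np.ndarray  # (L,) float64
    role: np.ndarray  # (L,) int8
    chr_lengths_cM: np.ndarray  # (n_chromosomes,) float64

    def __post_init__(self) -> None:
        if not (len(self.chrom) == len(self.pos_cM) == len(self.role)):
            raise ConfigurationError("map arrays must have equal length")
        if np.any(self.pos_cM < 0):
            raise ConfigurationError("genetic positions must be non-negative")
        for c in range(self.n_chromosomes):
            p = self.pos_cM[self.chrom == c]
            if len(p) and np.any(np.diff(p) <= 0):
                raise ConfigurationError(
                    f"positions not strictly increasing on chromosome {c}"
                )
        if np.any(np.diff(self.chrom) < 0):
            raise ConfigurationError("loci must be stored chromosome-major")

    @property
    def n_loci(self) -> int:
        return len(self.pos_cM)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chr_lengths_cM)

    @property
    def qtn_indices(self) -> np.ndarray:
        return np.flatnonzero(self.role == ROLE_QTN)

    @property
    def snp_indices(self) -> np.ndarray:
        return np.flatnonzero(self.role == ROLE_SNP)

    def chromosome_loci(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.chrom == c)

    def subset(self, keep: np.ndarray) -> "GeneticMap":
        """Restrict the map to a subset of loci (order preserved)."""
        keep = np.asarray(keep)
        return GeneticMap(
            chrom=self.chrom[keep],
            pos_cM=self.pos_cM[keep],
            role=self.role[keep],
            chr_lengths_cM=self.chr_lengths_cM.copy(),
        )


@dataclasses.dataclass
class HaplotypePopulation:
    """A set of diploid individuals as paired binary haplotypes over one map.

    ``haplotypes`` has shape (n, 2, L) with allele values in {0, 1}
    (A1 = 1, A2 = 0). ``family`` labels the cross of origin (-1 for founders);
    ``generation`` is one of founder, F1..F6+. Under single-seed descent the
    individual ``ids`` persist through selfing generations.
    """

    haplotypes: np.ndarray
    gmap: GeneticMap
    ids: np.ndarray
    family: np.ndarray
    generation: str

    def __post_init__(self) -> None:
        h = self.haplotypes
        if h.ndim != 3 or h.shape[1] != 2 or h.shape[2] != self.gmap.n_loci:
            raise ConfigurationError("haplotypes must have shape (n, 2, n_loci)")
        if h.dtype != np.uint8:
            self.haplotypes = h.astype(np.uint8)
        if len(self.ids) != h.shape[0] or len(self.family) != h.shape[0]:
            raise ConfigurationError("ids/family must match individual count")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ConfigurationError("individual ids must be unique")

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    def dosage(self) -> np.ndarray:
        """Genotype dosages with the -1/0/1 convention (A2A2, A1A2, A1A1)."""
        return self.haplotypes.sum(axis=1).astype(np.int8) - 1

    def allele_frequencies(self) -> np.ndarray:
        """Frequency of allele A1 per locus across all haplotypes."""
        return self.haplotypes.mean(axis=(0, 1))

    def heterozygosity(self) -> np.ndarray:
        """Per-individual fraction of heterozygous loci."""
        return (self.haplotypes[:, 0, :] != self.haplotypes[:, 1, :]).mean(axis=1)

    def is_fully_homozygous(self) -> bool:
        return bool(np.all(self.haplotypes[:, 0, :] == self.haplotypes[:, 1, :]))

    def subset(self, idx: np.ndarray) -> "HaplotypePopulation":
        idx = np.asarray(idx)
        return HaplotypePopulation(
            haplotypes=self.haplotypes[idx],
            gmap=self.gmap,
            ids=self.ids[idx],
            family=self.family[idx],
            generation=self.generation,
        )

    def write_dosage(self, path: str) -> None:
        """Plain-text dosage matrix (-1/0/1), one row per individual."""
        d = self.dosage()
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(f"L{j}" for j in range(d.shape[1])) + "\n")
            for i in range(d.shape[0]):
                fh.write(str(self.ids[i]) + "\t" + "\t".join(map(str, d[i])) + "\n")

    def write_vcf(self, path: str) -> None:
        """Minimal diploid VCF export (GT only, one contig per chromosome).

        Genetic positions are written as 1-based integer coordinates in
        centiMorgan units scaled by 100 to keep them distinct.
        """
        gmap = self.gmap
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in range(gmap.n_chromosomes):
                length = int(gmap.chr_lengths_cM[c] * 100) + 2
                fh.write(f"##contig=<ID=chr{c + 1},length={length}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            cols = "\t".join(str(i) for i in self.ids)
            fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
            h = self.haplotypes
            for j in range(gmap.n_loci):
                pos = int(round(gmap.pos_cM[j] * 100)) + 1
                gts = "\t".join(f"{h[i, 0, j]}|{h[i, 1, j]}" for i in range(self.n))
                fh.write(
                    f"chr{gmap.chrom[j] + 1}\t{pos}\tL{j}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
                )


def _allocate_loci(chr_lengths: np.ndarray, n_total: int) -> np.ndarray:
    """Largest-remainder allocation of loci to chromosomes, proportional to cM."""
    share = chr_lengths / chr_lengths.sum() * n_total
    counts = np.floor(share).astype(int)
    remainder = n_total - counts.sum()
    order = np.argsort(-(share - counts))
    counts[order[:remainder]] += 1
    return counts


def build_map(
    n_chromosomes: int = 12,
    chr_lengths_cM: Sequence[float] | None = None,
    n_loci_total: int = 1644,
    n_qtn_per_chr: int = 30,
    n_snp_per_chr: int = 45,
    seed: int | np.random.Generator | None = None,
) -> GeneticMap:
    """Build the genetic map with QTN and SNP roles assigned to disjoint loci.

    Loci are distributed across chromosomes proportionally to map length and
    placed on a uniform grid spanning each chromosome (endpoints included).
    SNPs are uniformly spaced among the chromosome's loci; QTNs are sampled
    without replacement from the remaining loci.
    """
    if chr_lengths_cM is None:
        chr_lengths_cM = [100.0] * n_chromosomes
    lengths = np.asarray(chr_lengths_cM, dtype=float)
    if len(lengths) != n_chromosomes:
        raise ConfigurationError("chr_lengths_cM length must equal n_chromosomes")
    if np.any(lengths <= 0):
        raise ConfigurationError("chromosome lengths must be positive")
    rng = _as_rng(seed)

    counts = _allocate_loci(lengths, n_loci_total)
    demand = n_qtn_per_chr + n_snp_per_chr
    for c, k in enumerate(counts):
        if k < demand:
            raise ConfigurationError(
                f"chromosome {c}: {k} loci cannot host {n_qtn_per_chr} QTN + "
                f"{n_snp_per_chr} SNP"
            )

    chrom_parts, pos_parts, role_parts = [], [], []
    for c, k in enumerate(counts):
        pos = np.linspace(0.0, lengths[c], k)
        role = np.full(k, ROLE_NEUTRAL, dtype=np.int8)
        if n_snp_per_chr > 0:
            snp_local = np.round(np.linspace(0, k - 1, n_snp_per_chr)).astype(int)
            role[snp_local] = ROLE_SNP
        if n_qtn_per_chr > 0:
            eligible = np.flatnonzero(role == ROLE_NEUTRAL)
            qtn_local = rng.choice(eligible, size=n_qtn_per_chr, replace=False)
            role[qtn_local] = ROLE_QTN
        chrom_parts.append(np.full(k, c, dtype=np.int16))
        pos_parts.append(pos)
        role_parts.append(role)

    return GeneticMap(
        chrom=np.concatenate(chrom_parts),
        pos_cM=np.concatenate(pos_parts),
        role=np.concatenate(role_parts),
        chr_lengths_cM=lengths,
    )


def _drop_site(tree, rng: np.random.Generator, n_samples: int, max_tries: int = 100):
    """Pick a branch proportional to its length; derived allele = leaves below.

    Any non-root branch subtends between 1 and n-1 samples, so the resulting
    site is polymorphic; the retry loop is a guard for degenerate trees.
    """
    nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
    lengths = np.array([tree.branch_length(u) for u in nodes])
    total = lengths.sum()
    if total <= 0 or not nodes:
        return None
    for _ in range(max_tries):
        u = nodes[rng.choice(len(nodes), p=lengths / total)]
        carriers = np.fromiter(tree.samples(u), dtype=np.int64)
        if 0 < len(carriers) < n_samples:
            return carriers
    return None


def simulate_founders(
    gmap: GeneticMap,
    n_founders: int = 1000,
    coalescent_params: dict | None = None,
    seed: int | np.random.Generator | None = None,
) -> HaplotypePopulation:
    """Simulate fully homozygous founder pure lines over the map.

    One haplotype per founder is sampled from a per-chromosome neutral
    coalescent (recombination rate 0.01 per cM, i.e. 1 Morgan = 100 cM) and
    doubled, mimicking fully inbred lines. Every locus is polymorphic across
    the founder haplotype sample by construction.
    """
    if n_founders < 2:
        raise ConfigurationError("need at least 2 founders")
    params = {"effective_population_size": 100.0, "model": "generic"}
    if coalescent_params:
        params.update(coalescent_params)
    rng = _as_rng(seed)
    ne = float(params["effective_population_size"])
    if params["model"] == "generic":
        # generic-crop demography: recent Ne with stepwise ancestral
        # expansion (times in 4·Ne generations, sizes as multiples of Ne)
        demography = msprime.Demography()
        demography.add_population(initial_size=ne)
        for t4n, mult in [(0.25, 5), (2.5, 15), (25, 60), (250, 120), (2500, 1000)]:
            demography.add_population_parameters_change(
                time=4 * ne * t4n, initial_size=mult * ne
            )
    elif params["model"] == "constant":
        demography = msprime.Demography()
        demography.add_population(initial_size=ne)
    else:
        raise ConfigurationError(f"unknown coalescent model {params['model']!r}")

    H = np.zeros((n_founders, gmap.n_loci), dtype=np.uint8)
    for c in range(gmap.n_chromosomes):
        loci = gmap.chromosome_loci(c)
        length = float(gmap.chr_lengths_cM[c])
        ts = msprime.sim_ancestry(
            samples=n_founders,
            ploidy=1,
            demography=demography,
            sequence_length=length,
            recombination_rate=0.01,
            discrete_genome=False,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        for j in loci:
            pos = min(gmap.pos_cM[j], np.nextafter(length, 0.0))
            tree = ts.at(pos)
            carriers = _drop_site(tree, rng, n_founders)
            if carriers is None:
                raise SimulationError(
                    f"could not obtain a polymorphic site at locus {j} "
                    f"(chromosome {c}, {gmap.pos_cM[j]:.3f} cM)"
                )
            H[carriers, j] = 1

    hap = np.stack([H, H], axis=1)
    return HaplotypePopulation(
        haplotypes=hap,
        gmap=gmap,
        ids=np.arange(n_founders, dtype=np.int64),
        family=np.full(n_founders, -1, dtype=np.int64),
        generation="founder",
    )


def next_generation_label(label: str) -> str:
    """F-generation bookkeeping: founder→F1, F1→F2, ..."""
    if label == "founder":
        return "F1"
    if label.startswith("F"):
        return f"F{int(label[1:]) + 1}"
    raise ConfigurationError(f"unknown generation label: {label}")
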