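"""Meiosis, crossing, and selfing on a centiMorgan map.

Recombination follows the Haldane model: per chromosome the crossover count is
Poisson with mean equal to the map length in Morgans, crossover positions are
uniform along the chromosome, and there is no interference. Selfing uses
single-seed descent (one selfed offspring per line per generation), the
standard way inbred generations F2→F6 are advanced in line breeding.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .genome_founders import (
    ConfigurationError,
    GeneticMap,
    HaplotypePopulation,
    _as_rng,
    next_generation_label,
)

__all__ = [
    "CrossPlan",
    "meiosis",
    "make_crosses",
    "self_advance",
    "self_progeny",
    "random_cross_plan",
]


@dataclasses.dataclass(frozen=True)
class CrossPlan:
    """(mother, father, n_progeny) triples referring to individual ids."""

    mother: np.ndarray
    father: np.ndarray
    n_progeny: np.ndarray
    generation: str = "F1"

    def __post_init__(self) -> None:
        if not (len(self.mother) == len(self.father) == len(self.n_progeny)):
            raise ConfigurationError("cross plan arrays must have equal length")
        if np.any(self.n_progeny < 1):
            raise ConfigurationError("n_progeny must be >= 1 for every cross")

    @property
    def n_crosses(self) -> int:
        return len(self.mother)

    @property
    def total_progeny(self) -> int:
        return int(self.n_progeny.sum())


def _batch_gametes(
    haps: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete per input individual, vectorized over meioses.

    For each meiosis and chromosome, the source haplotype at a locus is the
    starting haplotype flipped once per crossover occurring left of the locus.
    """
    n = haps.shape[0]
    out = np.empty((n, gmap.n_loci), dtype=np.uint8)
    for c in range(gmap.n_chromosomes):
        loci = gmap.chromosome_loci(c)
        pos = gmap.pos_cM[loci]
        length = float(gmap.chr_lengths_cM[c])
        k = rng.poisson(length / 100.0, size=n)
        kmax = int(k.max()) if n else 0
        start = rng.integers(0, 2, size=n).astype(bool)
        if kmax == 0:
            src = np.broadcast_to(start[:, None], (n, len(loci)))
        else:
            xo = rng.uniform(0.0, length, size=(n, kmax))
            xo[np.arange(kmax)[None, :] >= k[:, None]] = np.inf
            # source haplotype = start flipped once per crossover left of the
            # locus: only the parity of the crossover count matters
            parity = np.zeros((n, len(loci)), dtype=bool)
            for col in range(kmax):
                parity ^= xo[:, col : col + 1] < pos[None, :]
            src = start[:, None] ^ parity
        h = haps[:, :, loci]
        out[:, loci] = np.where(src, h[:, 1, :], h[:, 0, :])
    return out


def meiosis(
    parent: np.ndarray, gmap: GeneticMap, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Single gamete from one parent's (2, L) haplotype pair."""
    if parent.shape != (2, gmap.n_loci):
        raise ConfigurationError("parent haplotypes must have shape (2, n_loci)")
    rng = _as_rng(seed)
    return _batch_gametes(parent[None, :, :], gmap, rng)[0]


def make_crosses(
    pop: HaplotypePopulation,
    plan: CrossPlan,
    seed: int | np.random.Generator | None = None,
) -> HaplotypePopulation:
    """Progeny from a cross plan: one maternal + one paternal gamete each.

    Families are labelled by cross index within the plan; progeny ids are
    fresh consecutive integers.
    """
    rng = _as_rng(seed)
    id_to_row = {int(i): r for r, i in enumerate(pop.ids)}
    for parent_id in np.concatenate([plan.mother, plan.father]):
        if int(parent_id) not in id_to_row:
            raise ConfigurationError(f"unknown parent id {parent_id}")

    reps = plan.n_progeny.astype(int)
    mrow = np.repeat([id_to_row[int(i)] for i in plan.mother], reps)
    frow = np.repeat([id_to_row[int(i)] for i in plan.father], reps)
    fam = np.repeat(np.arange(plan.n_crosses, dtype=np.int64), reps)

    mg = _batch_gametes(pop.haplotypes[mrow], pop.gmap, rng)
    fg = _batch_gametes(pop.haplotypes[frow], pop.gmap, rng)
    return HaplotypePopulation(
        haplotypes=np.stack([mg, fg], axis=1),
        gmap=pop.gmap,
        ids=np.arange(len(mrow), dtype=np.int64),
        family=fam,
        generation=plan.generation,
    )


def self_progeny(
    pop: HaplotypePopulation,
    n_per_individual: int,
    seed: int | np.random.Generator | None = None,
) -> HaplotypePopulation:
    """n selfed offspring per individual (family = parent's family label)."""
    rng = _as_rng(seed)
    rows = np.repeat(np.arange(pop.n), n_per_individual)
    g1 = _batch_gametes(pop.haplotypes[rows], pop.gmap, rng)
    g2 = _batch_gametes(pop.haplotypes[rows], pop.gmap, rng)
    return HaplotypePopulation(
        haplotypes=np.stack([g1, g2], axis=1),
        gmap=pop.gmap,
        ids=np.arange(len(rows), dtype=np.int64),
        family=pop.family[rows].copy(),
        generation=next_generation_label(pop.generation),
    )


def self_advance(
    pop: HaplotypePopulation,
    n_generations: int,
    seed: int | np.random.Generator | None = None,
) -> HaplotypePopulation:
    """Advance by selfing under single-seed descent.

    Each line is replaced by one selfed descendant per generation; ids and
    family labels persist so lines can be tracked across generations.
    """
    if n_generations < 1:
        raise ConfigurationError("n_generations must be >= 1")
    rng = _as_rng(seed)
    out = pop
    for _ in range(n_generations):
        g1 = _batch_gametes(out.haplotypes, out.gmap, rng)
        g2 = _batch_gametes(out.haplotypes, out.gmap, rng)
        out = HaplotypePopulation(
            haplotypes=np.stack([g1, g2], axis=1),
            gmap=out.gmap,
            ids=out.ids.copy(),
            family=out.family.copy(),
            generation=next_generation_label(out.generation),
        )
    return out


def random_cross_plan(
    pop: HaplotypePopulation,
    n_crosses: int,
    progeny_per_cross: int,
    seed: int | np.random.Generator | None = None,
) -> CrossPlan:
    """Random biparental pairs from a population.

    Parents are paired without replacement when the pool allows
    (2·n_crosses ≤ n), otherwise pairs are drawn uniformly at random with
    replacement, excluding self-pairs; budget schemes need up to 160 crosses
    from 40 parents.
    """
    if pop.n < 2:
        raise ConfigurationError("need at least 2 candidate parents")
    rng = _as_rng(seed)
    if 2 * n_crosses <= pop.n:
        chosen = rng.choice(pop.ids, size=2 * n_crosses, replace=False)
        mother, father = chosen[:n_crosses], chosen[n_crosses:]
    else:
        mother = rng.choice(pop.ids, size=n_crosses, replace=True)
        father = rng.choice(pop.ids, size=n_crosses, replace=True)
        clash = mother == father
        while np.any(clash):
            father[clash] = rng.choice(pop.ids, size=int(clash.sum()), replace=True)
            clash = mother == father
    return CrossPlan(
        mother=mother,
        father=father,
        n_progeny=np.full(n_crosses, progeny_per_cross, dtype=np.int64),
    )
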