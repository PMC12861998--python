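"""Burn-in pedigree scheme and the 10-cycle test-and-shelf GS program.

Burn-in: three 5-year cycles of phenotypic pedigree selection (160 random
crosses, F2 families of 100, truncation on phenotype at F2/F3/F4, 40 new
parents chosen at F5), totalling 15 years and establishing the base
population for each epistasis level.

GS scheme (one 5-year cycle): random crosses among the 40 current parents
are advanced to F2; a random 20% of the F2 census forms the *test* group,
the remaining 80% the *shelf*. The test group is selfed to F5 and phenotyped;
a two-kernel GBLUP (additive + additive×additive) is fitted on the test set
with F2 marker genotypes, and shelf individuals are predicted at F2 by
kriging projection. The best 32 shelf individuals on predicted value (80% of
the 40 parents) are advanced to F5 and joined by the 8 best test individuals
on F5 phenotype; all 40 are selfed to F6 to form the next cycle's parents,
and the best F6 line (on phenotype) is recorded.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import grm_gblup, reproduction, trait_model
from .genome_founders import ConfigurationError, HaplotypePopulation, _as_rng
from .metrics_stats import CycleRecord, accuracy, variance_components_true

__all__ = [
    "BurninConfig",
    "SchemeConfig",
    "ProgramState",
    "run_burnin",
    "run_gs_cycle",
    "run_program",
]


@dataclasses.dataclass(frozen=True)
class BurninConfig:
    """Pedigree burn-in settings.

    ``n_candidates`` lines are advanced from F2 to F5 by random single-seed
    descent each cycle (a pedigree program phenotypes only a few hundred F5
    lines); truncation on phenotype happens at F5 (top ``n_parents``), with an
    optional additional phenotypic culling at F2 via ``f2_keep_fraction``.
    The default candidate pool is calibrated so that the 15-year burn-in
    lifts the base population by ≈2.4 founder genetic SD (see methods note).
    """

    n_cycles: int = 3
    n_crosses: int = 160
    progeny_per_cross: int = 100
    n_candidates: int = 150
    f2_keep_fraction: float | None = None
    n_parents: int = 40
    years_per_cycle: int = 5

    @property
    def total_years(self) -> int:
        return self.n_cycles * self.years_per_cycle


@dataclasses.dataclass(frozen=True)
class SchemeConfig:
    context: str  # "theoretical" | "budget"
    progeny_per_cross: int
    n_crosses: int
    n_parents: int = 40
    test_fraction: float = 0.20
    n_test_selected: int = 8
    shelf_selection_rule: float = 0.80  # fraction of parents taken from shelf
    n_cycles: int = 10
    budget_F2_cap: int = 4000
    years_per_cycle: int = 5
    min_test_size: int = 20
    max_training_size: int | None = None  # genotyping budget for the GBLUP fit

    def __post_init__(self) -> None:
        if self.context not in ("theoretical", "budget"):
            raise ConfigurationError(f"unknown context {self.context!r}")
        if self.context == "budget":
            if self.n_crosses * self.progeny_per_cross != self.budget_F2_cap:
                raise ConfigurationError(
                    "budget context requires n_crosses × progeny_per_cross "
                    f"= {self.budget_F2_cap}, got "
                    f"{self.n_crosses} × {self.progeny_per_cross}"
                )
        if self.n_test_selected + self.n_shelf_selected != self.n_parents:
            raise ConfigurationError(
                "test + shelf selections must equal the parent count"
            )

    @property
    def n_shelf_selected(self) -> int:
        return round(self.shelf_selection_rule * self.n_parents)

    @property
    def f2_census(self) -> int:
        return self.n_crosses * self.progeny_per_cross


@dataclasses.dataclass
class ProgramState:
    parents: HaplotypePopulation
    cycle: int
    records: list[CycleRecord]
    rng: np.random.Generator


def _select_top(pop: HaplotypePopulation, values: np.ndarray, k: int):
    """Indices of the k largest values (truncation selection)."""
    if k > pop.n:
        raise ConfigurationError(
            f"selection demand {k} exceeds {pop.n} candidates"
        )
    return np.argsort(values)[::-1][:k]


def _f2_population(parents, n_crosses, progeny_per_cross, rng):
    """Cross → single F1 per cross → selfed F2 family of the requested size."""
    plan = reproduction.random_cross_plan(parents, n_crosses, 1, rng)
    f1 = reproduction.make_crosses(parents, plan, rng)
    return reproduction.self_progeny(f1, progeny_per_cross, rng)


def run_burnin(
    founders: HaplotypePopulation,
    arch: trait_model.TraitArchitecture,
    config: BurninConfig = BurninConfig(),
    seed: int | np.random.Generator | None = None,
) -> tuple[HaplotypePopulation, dict]:
    """Phenotypic pedigree selection establishing the base parents.

    Returns the base parents (F5 lines of the last burn-in cycle) and the
    cycle-0 reference statistics computed on them (Ḡ₀, Va₀, Vaa₀, plus the
    best F6 line of the final cycle).
    """
    rng = _as_rng(seed)
    pool = founders
    best_line_G = np.nan
    for _ in range(config.n_cycles):
        pop = _f2_population(pool, config.n_crosses, config.progeny_per_cross, rng)
        if config.f2_keep_fraction is not None:
            y2 = trait_model.phenotype(pop, arch, rng).phenotypes
            keep = max(
                int(round(config.f2_keep_fraction * pop.n)), config.n_candidates
            )
            pop = pop.subset(_select_top(pop, y2, keep))
        n_cand = min(config.n_candidates, pop.n)
        if n_cand < config.n_parents:
            raise ConfigurationError(
                f"candidate pool {n_cand} smaller than parent demand "
                f"{config.n_parents}"
            )
        cand = rng.choice(pop.n, size=n_cand, replace=False)
        pop = reproduction.self_advance(pop.subset(cand), 3, rng)
        y5 = trait_model.phenotype(pop, arch, rng).phenotypes
        parents = pop.subset(_select_top(pop, y5, config.n_parents))
        f6 = reproduction.self_advance(parents, 1, rng)
        y6 = trait_model.phenotype(f6, arch, rng).phenotypes
        best_line_G = float(
            trait_model.genetic_value(f6, arch).genetic_values[np.argmax(y6)]
        )
        pool = parents

    g_parents = trait_model.genetic_value(pool, arch).genetic_values
    va0, vaa0 = variance_components_true(pool, arch)
    baseline = {
        "mean_G": float(g_parents.mean()),
        "Va": va0,
        "Vaa": vaa0,
        "best_line_G": best_line_G,
        "burnin_years": config.total_years,
    }
    return pool, baseline


def run_gs_cycle(
    state: ProgramState,
    arch: trait_model.TraitArchitecture,
    config: SchemeConfig,
    seed: int | np.random.Generator | None = None,
) -> tuple[ProgramState, CycleRecord]:
    """One 5-year test-and-shelf genomic-selection cycle."""
    rng = _as_rng(seed) if seed is not None else state.rng
    if state.parents.n != config.n_parents:
        raise ConfigurationError(
            f"expected {config.n_parents} parents, found {state.parents.n}"
        )

    # (1) crosses → F2 census
    f2 = _f2_population(state.parents, config.n_crosses, config.progeny_per_cross, rng)
    g_f2 = trait_model.genetic_value(f2, arch).genetic_values
    va, vaa = variance_components_true(f2, arch)

    # (2) random test/shelf split of the F2 census
    n_test = int(round(config.test_fraction * f2.n))
    if n_test < config.min_test_size:
        raise ConfigurationError(
            f"test set of {n_test} below the REML minimum {config.min_test_size}"
        )
    perm = rng.permutation(f2.n)
    test_idx, shelf_idx = perm[:n_test], perm[n_test:]

    # kernels defined on the union (all F2: centering and trace normalizers
    # use the whole census), with only the needed blocks materialized
    M, _ = grm_gblup.code_and_center(f2)
    row_sq = np.einsum("ij,ij->i", M, M)
    s_a = row_sq.mean()  # tr(MMᵀ)/n over the union

    # (3) test group selfed to F5, phenotyped, GBLUP fitted on F2 genotypes;
    #     the training set is the test group, optionally capped at a random
    #     genotyping-budget subset
    test_f5 = reproduction.self_advance(f2.subset(test_idx), 3, rng)
    y_test = trait_model.phenotype(test_f5, arch, rng).phenotypes
    if config.max_training_size is not None and config.max_training_size < n_test:
        train_local = rng.choice(n_test, size=config.max_training_size, replace=False)
    else:
        train_local = np.arange(n_test)
    train_idx = test_idx[train_local]
    y_train = y_test[train_local]
    degenerate = s_a <= 1e-12 or y_train.var() <= 1e-12
    if degenerate:
        # markers (or training phenotypes) carry no variance — typically
        # late-cycle fixation; the model has no information beyond the mean
        fit = None
        yhat_shelf = np.full(len(shelf_idx), float(y_train.mean()))
    else:
        s_aa = np.mean((row_sq / s_a) ** 2)  # tr(Ga∘Ga)/n over the union
        Mt, Ms = M[train_idx], M[shelf_idx]
        Ga_tt = Mt @ Mt.T / s_a
        Ga_ts = Mt @ Ms.T / s_a
        Gaa_tt = Ga_tt**2 / s_aa
        Gaa_ts = Ga_ts**2 / s_aa
        fit = grm_gblup.fit_reml(y_train, Ga_tt, Gaa_tt)

        # (4) shelf predicted at F2 by kriging; truncation on predicted value
        yhat_shelf, _, _ = grm_gblup.project_to_shelf(
            fit, Ga_ts, Gaa_ts, Ga_tt, Gaa_tt
        )
    if np.std(yhat_shelf) == 0 or np.std(g_f2[shelf_idx]) == 0:
        rho = np.nan
    else:
        rho = accuracy(g_f2[shelf_idx], yhat_shelf)
    shelf_pop = f2.subset(shelf_idx)
    shelf_sel = shelf_pop.subset(_select_top(shelf_pop, yhat_shelf, config.n_shelf_selected))
    shelf_f5 = reproduction.self_advance(shelf_sel, 3, rng)

    # (5) best test individuals on F5 phenotype join the selected shelf;
    #     everything selfed to F6 to form the new parents
    best_test = test_f5.subset(_select_top(test_f5, y_test, config.n_test_selected))
    joint = HaplotypePopulation(
        haplotypes=np.concatenate([best_test.haplotypes, shelf_f5.haplotypes]),
        gmap=f2.gmap,
        ids=np.arange(best_test.n + shelf_f5.n, dtype=np.int64),
        family=np.concatenate([best_test.family, shelf_f5.family]),
        generation="F5",
    )
    new_parents = reproduction.self_advance(joint, 1, rng)

    # (6) best F6 line on phenotype; true G recorded
    y6 = trait_model.phenotype(new_parents, arch, rng).phenotypes
    g6 = trait_model.genetic_value(new_parents, arch).genetic_values
    best_line_G = float(g6[np.argmax(y6)])

    cycle = state.cycle + 1
    record = CycleRecord(
        replicate=-1,
        cycle=cycle,
        year=cycle * config.years_per_cycle,
        context=config.context,
        progeny_size=config.progeny_per_cross,
        epistasis_ratio=arch.epistasis_ratio,
        mean_G=float(g_f2.mean()),
        best_line_G=best_line_G,
        Va=va,
        Vaa=vaa,
        accuracy=rho,
        parents_mean_G=float(g6.mean()),
        sigma_a2_hat=fit.sigma_a2 if fit else np.nan,
        sigma_aa2_hat=fit.sigma_aa2 if fit else np.nan,
        sigma_e2_hat=fit.sigma_e2 if fit else np.nan,
    )
    new_state = ProgramState(
        parents=new_parents, cycle=cycle, records=state.records + [record], rng=rng
    )
    return new_state, record


def baseline_record(
    base_parents: HaplotypePopulation,
    arch: trait_model.TraitArchitecture,
    config: SchemeConfig,
    burnin_stats: dict | None = None,
) -> CycleRecord:
    """Cycle-0 reference record computed on the base parents."""
    if burnin_stats is None:
        g = trait_model.genetic_value(base_parents, arch).genetic_values
        va, vaa = variance_components_true(base_parents, arch)
        burnin_stats = {
            "mean_G": float(g.mean()),
            "Va": va,
            "Vaa": vaa,
            "best_line_G": float(g.max()),
        }
    return CycleRecord(
        replicate=-1,
        cycle=0,
        year=0,
        context=config.context,
        progeny_size=config.progeny_per_cross,
        epistasis_ratio=arch.epistasis_ratio,
        mean_G=burnin_stats["mean_G"],
        best_line_G=burnin_stats["best_line_G"],
        Va=burnin_stats["Va"],
        Vaa=burnin_stats["Vaa"],
        accuracy=np.nan,
        parents_mean_G=burnin_stats["mean_G"],
    )


def run_program(
    base_parents: HaplotypePopulation,
    arch: trait_model.TraitArchitecture,
    config: SchemeConfig,
    seed: int | np.random.Generator | None = None,
    burnin_stats: dict | None = None,
) -> list[CycleRecord]:
    """Run n_cycles sequential GS cycles from the burn-in base.

    Returns the baseline (cycle-0) record followed by one record per cycle;
    deterministic given the seed.
    """
    rng = _as_rng(seed)
    records = [baseline_record(base_parents, arch, config, burnin_stats)]
    state = ProgramState(parents=base_parents, cycle=0, records=records, rng=rng)
    for _ in range(config.n_cycles):
        state, _rec = run_gs_cycle(state, arch, config)
    return state.records
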