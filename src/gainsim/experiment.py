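"""Scenario-grid orchestration: replicates, seeding, persistence, resume.

The study design is a full factorial of context {theoretical, budget} ×
progeny size {25, 50, 100, 200} × epistasis ratio {0, 0.5, 1.0}, replicated
with independent founder populations, trait architectures and burn-ins.
Within a replicate, the same base population (per epistasis level) is reused
across all progeny sizes and contexts, which couples the comparisons and
removes between-base variance from the size contrasts.

Two scale presets are provided: ``full`` mirrors the study design
(1000 founders, 1644 loci, 100 replicates, uncapped training sets) and
``reduced`` is a desk-scale configuration (300 founders, 600 loci, 10
replicates, training sets capped at 300) with the full scheme geometry,
suited to a single CPU; see docs/methods.md for the rationale.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np
import pandas as pd

from . import breeding_program, genome_founders, metrics_stats, trait_model
from .genome_founders import ConfigurationError

__all__ = [
    "ScalePreset",
    "ScenarioGrid",
    "SCALE_PRESETS",
    "derive_seed",
    "expand_grid",
    "prepare_base",
    "run_scenario_replicate",
    "run_grid",
]

DEFAULT_SIZES = (25, 50, 100, 200)
DEFAULT_EPISTASIS = (0.0, 0.5, 1.0)


@dataclasses.dataclass(frozen=True)
class ScalePreset:
    name: str
    n_founders: int
    n_chromosomes: int
    n_loci: int
    n_qtn_per_chr: int
    n_snp_per_chr: int
    theoretical_crosses: int
    budget_F2_cap: int
    n_replicates: int
    n_cycles: int
    burnin: breeding_program.BurninConfig
    founder_Ne: float = 100.0
    target_H2: float = 0.63
    max_training_size: int | None = None


SCALE_PRESETS = {
    "full": ScalePreset(
        name="full",
        n_founders=1000,
        n_chromosomes=12,
        n_loci=1644,
        n_qtn_per_chr=30,
        n_snp_per_chr=45,
        theoretical_crosses=40,
        budget_F2_cap=4000,
        n_replicates=100,
        n_cycles=10,
        burnin=breeding_program.BurninConfig(),
    ),
    "reduced": ScalePreset(
        name="reduced",
        n_founders=300,
        n_chromosomes=12,
        n_loci=600,
        n_qtn_per_chr=10,
        n_snp_per_chr=15,
        theoretical_crosses=40,
        budget_F2_cap=4000,
        n_replicates=10,
        n_cycles=10,
        burnin=breeding_program.BurninConfig(),
        max_training_size=300,
    ),
}


@dataclasses.dataclass(frozen=True)
class ScenarioGrid:
    contexts: tuple[str, ...] = ("theoretical", "budget")
    progeny_sizes: tuple[int, ...] = DEFAULT_SIZES
    epistasis_ratios: tuple[float, ...] = DEFAULT_EPISTASIS
    n_replicates: int | None = None  # None → preset default
    master_seed: int = 1
    scale: str = "reduced"
    n_cycles: int | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALE_PRESETS:
            raise ConfigurationError(f"unknown scale preset {self.scale!r}")
        preset = SCALE_PRESETS[self.scale]
        for ctx in self.contexts:
            if ctx not in ("theoretical", "budget"):
                raise ConfigurationError(f"unknown context {ctx!r}")
            for size in self.progeny_sizes:
                if ctx == "budget" and preset.budget_F2_cap % size != 0:
                    raise ConfigurationError(
                        f"progeny size {size} does not divide the F2 cap "
                        f"{preset.budget_F2_cap}"
                    )

    @property
    def preset(self) -> ScalePreset:
        return SCALE_PRESETS[self.scale]

    @property
    def replicates(self) -> int:
        return self.n_replicates if self.n_replicates is not None else self.preset.n_replicates

    @property
    def cycles(self) -> int:
        return self.n_cycles if self.n_cycles is not None else self.preset.n_cycles


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic, non-overlapping seed stream from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _cross_count(ctx: str, size: int, preset: ScalePreset) -> int:
    if ctx == "theoretical":
        return preset.theoretical_crosses
    return preset.budget_F2_cap // size


def expand_grid(grid: ScenarioGrid) -> list[breeding_program.SchemeConfig]:
    """Full factorial expansion into resolved scheme configurations.

    Epistasis is a property of the base population, not of the scheme, so the
    expansion enumerates (context, size) schemes; callers pair each with every
    epistasis level.
    """
    preset = grid.preset
    configs = []
    for ctx in grid.contexts:
        for size in grid.progeny_sizes:
            configs.append(
                breeding_program.SchemeConfig(
                    context=ctx,
                    progeny_per_cross=size,
                    n_crosses=_cross_count(ctx, size, preset),
                    n_cycles=grid.cycles,
                    budget_F2_cap=preset.budget_F2_cap,
                    max_training_size=preset.max_training_size,
                )
            )
    return configs


def prepare_base(
    preset: ScalePreset, master_seed: int, replicate: int, epistasis_ratio: float
):
    """Founders + calibrated architecture + burn-in base for one replicate.

    Founder genotypes depend on the replicate only; the trait architecture and
    the burn-in depend additionally on the epistasis level.
    """
    eps_key = int(round(epistasis_ratio * 100))
    gmap = genome_founders.build_map(
        n_chromosomes=preset.n_chromosomes,
        n_loci_total=preset.n_loci,
        n_qtn_per_chr=preset.n_qtn_per_chr,
        n_snp_per_chr=preset.n_snp_per_chr,
        seed=derive_seed(master_seed, 0, replicate),
    )
    founders = genome_founders.simulate_founders(
        gmap,
        n_founders=preset.n_founders,
        coalescent_params={"effective_population_size": preset.founder_Ne},
        seed=derive_seed(master_seed, 1, replicate),
    )
    arch = trait_model.sample_architecture(
        gmap,
        founders,
        epistasis_ratio=epistasis_ratio,
        target_H2=preset.target_H2,
        seed=derive_seed(master_seed, 2, replicate, eps_key),
    )
    base, stats = breeding_program.run_burnin(
        founders,
        arch,
        preset.burnin,
        seed=derive_seed(master_seed, 3, replicate, eps_key),
    )
    return founders, arch, base, stats


def run_scenario_replicate(
    config: breeding_program.SchemeConfig,
    arch: trait_model.TraitArchitecture,
    base,
    stats: dict,
    master_seed: int,
    replicate: int,
) -> list[metrics_stats.CycleRecord]:
    eps_key = int(round(arch.epistasis_ratio * 100))
    ctx_key = 0 if config.context == "theoretical" else 1
    seed = derive_seed(
        master_seed, 4, replicate, eps_key, ctx_key, config.progeny_per_cross
    )
    records = breeding_program.run_program(base, arch, config, seed, stats)
    for rec in records:
        rec.replicate = replicate
        rec.seed = seed
    return records


def _completed_runs(df: pd.DataFrame, n_cycles: int) -> set[tuple]:
    done = set()
    keys = ["context", "progeny_size", "epistasis_ratio", "replicate"]
    for key, sub in df.groupby(keys):
        if sub["cycle"].max() >= n_cycles:
            done.add(key)
    return done


def run_grid(
    grid: ScenarioGrid,
    out_path: str | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Execute all scenario × replicate runs; optionally persist and resume.

    Output metrics are independent of execution order: every run draws from
    its own seed stream derived from (master seed, replicate, epistasis,
    context, size). When ``out_path`` exists, completed (scenario, replicate)
    pairs found there are skipped and the table is extended in place.
    """
    preset = grid.preset
    configs = expand_grid(grid)
    existing = None
    done: set[tuple] = set()
    if out_path and os.path.exists(out_path):
        existing = pd.read_csv(out_path)
        done = _completed_runs(existing, grid.cycles)

    rows: list[dict] = []
    manifest: list[str] = []
    for replicate in range(grid.replicates):
        for eps in grid.epistasis_ratios:
            needed = [
                cfg
                for cfg in configs
                if (cfg.context, cfg.progeny_per_cross, float(eps), replicate)
                not in done
            ]
            if not needed:
                continue
            _, arch, base, stats = prepare_base(preset, grid.master_seed, replicate, eps)
            for cfg in needed:
                records = run_scenario_replicate(
                    cfg, arch, base, stats, grid.master_seed, replicate
                )
                rows.extend(r.to_dict() for r in records)
                manifest.append(
                    f"{cfg.context}\tsize={cfg.progeny_per_cross}\teps={eps}\t"
                    f"rep={replicate}\tseed={records[-1].seed}\tok"
                )
                if progress:
                    print(
                        f"[gainsim] {cfg.context} size={cfg.progeny_per_cross} "
                        f"eps={eps} rep={replicate} done"
                    )

    df = pd.DataFrame(rows, columns=metrics_stats.RECORD_COLUMNS)
    if existing is not None and len(existing):
        df = pd.concat([existing, df], ignore_index=True)
    df = df.sort_values(
        ["context", "progeny_size", "epistasis_ratio", "replicate", "cycle"]
    ).reset_index(drop=True)

    if out_path:
        os.makedirs(os.path.dirname(os.path.abspath(out_path)), exist_ok=True)
        df.to_csv(out_path, index=False)
        try:
            df.to_parquet(os.path.splitext(out_path)[0] + ".parquet")
        except (ImportError, OSError):  # columnar copy is best-effort
            pass
        from . import __version__

        with open(out_path + ".manifest.txt", "w") as fh:
            fh.write(f"gainsim {__version__}\n")
            fh.write(f"master_seed={grid.master_seed}\nscale={grid.scale}\n")
            fh.write(f"contexts={','.join(grid.contexts)}\n")
            fh.write(f"sizes={','.join(map(str, grid.progeny_sizes))}\n")
            fh.write(f"epistasis={','.join(map(str, grid.epistasis_ratios))}\n")
            fh.write(f"replicates={grid.replicates}\ncycles={grid.cycles}\n")
            fh.write("\n".join(manifest) + "\n")
    return df


def load_grid_config(path: str) -> ScenarioGrid:
    """Scenario configuration from a plain-text key-value (YAML) file."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "contexts" in raw:
        kwargs["contexts"] = tuple(raw["contexts"])
    if "progeny_sizes" in raw:
        kwargs["progeny_sizes"] = tuple(int(s) for s in raw["progeny_sizes"])
    if "epistasis_ratios" in raw:
        kwargs["epistasis_ratios"] = tuple(float(e) for e in raw["epistasis_ratios"])
    for key in ("n_replicates", "master_seed", "n_cycles"):
        if key in raw:
            kwargs[key] = int(raw[key])
    if "scale" in raw:
        kwargs["scale"] = str(raw["scale"])
    return ScenarioGrid(**kwargs)
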