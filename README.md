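# gainsim

Stochastic simulation of long-term genomic selection (GS) in a self-pollinated
crop. `gainsim` models a rice-like line-breeding program over 10 five-year
selection cycles and asks the design questions breeders face when adopting GS:

* How large should each biparental family (progeny size: 25, 50, 100 or 200
  F2 individuals per cross) be?
* How should a fixed F2 budget (4000 plants per cycle) be split between the
  number of crosses and the individuals per cross?
* How do additive×additive epistasis levels (Vaa/Va = 0, 0.5, 1.0) change the
  answers?

The package is aimed at quantitative geneticists and breeding-program
designers who want a tested, seedable, configurable re-implementation of this
simulation study — every stage (founders, trait, meiosis, GBLUP, scheme,
statistics) is an importable module with its own unit and property tests.

## Model

**Founders.** 1000 fully homozygous pure lines on 12 chromosomes (100 cM
each), carrying 1644 biallelic segregating sites of which 360 are causal QTNs
(30/chromosome) and 540 are SNP markers (45/chromosome, disjoint from QTNs).
Haplotypes come from a neutral coalescent (msprime) with a generic-crop
demography (recent Ne = 100 with stepwise ancestral expansion); one mutation
is dropped per map locus on a branch of the local genealogy chosen
proportional to branch length.

**Trait.** True genetic value of individual *i*:

    G_i = Σ_k a_k x_ik + Σ_(k,l) a_kl x_ik x_il ,     Y_i = μ + G_i + ε_i ,
    ε_i ~ N(0, σ_e²)

with x_ik centered −1/0/1 QTN dosages, disjoint random epistatic pairs, the
founder population standardized to mean(G) = 0 and Var(G) = 1 (responses are
in founder genetic-SD units), Vaa/Va calibrated exactly to the requested
epistasis level, and σ_e² set so founder broad-sense heritability H² ≈ 0.63.

**Genomic prediction.** Two-kernel GBLUP

    y = Xβ + Z_a a + Z_aa aa + ε ,   a ~ N(0, G_a σ_a²),  aa ~ N(0, G_aa′ σ_aa²)

with the VanRaden additive GRM G_a = MMᵀ/(tr(MMᵀ)/n) from the centered marker
matrix M, the epistatic kernel G_aa′ the trace-normalized Hadamard square
G_a∘G_a, variance components by Newton–Raphson REML, and shelf predictions by
kriging: ŷ(shelf) = mu + Σ_c K_cross,cᵀ K_test,c⁻ ĝ_c(test).

**Scheme.** After a 15-year phenotypic burn-in, each GS cycle crosses 40
parents, splits the F2 census into 20% *test* / 80% *shelf*, selfs the test
group to F5 for phenotyping and GBLUP training (F2 marker genotypes), selects
32 shelf individuals on projected predictions plus the 8 best test
individuals on phenotype, and selfs all 40 to F6 as the next cycle's parents.
Outputs per cycle: population mean G, best line, true Va and Vaa, shelf
prediction accuracy ρ = cor(G, Ĝ), parents' mean, REML estimates; responses
R_t = Ḡ_t(parents) − Ḡ_0 and R_t^(%/yr) = (100/t)·(Ḡ_t − Ḡ_0)/|Ḡ_0|.

## Worked example

```python
from gainsim import experiment as ex, metrics_stats as ms

grid = ex.ScenarioGrid(
    contexts=("theoretical",),
    progeny_sizes=(25, 200),
    epistasis_ratios=(0.0,),
    n_replicates=3,
    master_seed=7,
    scale="reduced",          # desk-scale preset: 300 founders, 600 loci
)
df = ex.run_grid(grid)
summary = ms.summarize_records(df)
cols = ["progeny_size", "cycle", "response_mean", "response_pct_yr_mean", "accuracy_mean"]
print(summary.loc[summary.cycle.isin([1, 10]), cols].to_string(index=False))
```

prints (seed 7):

```
 progeny_size  cycle  response_mean  response_pct_yr_mean  accuracy_mean
           25      1       0.744832              6.142623       0.602084
           25     10       4.121445              3.233427       0.175090
          200      1       1.214685              9.163352       0.556994
          200     10       4.591954              3.561723       0.059979
```

Reading the rows: size-200 families gain more per cycle early (1.21 vs 0.74
founder genetic SD at cycle 1) and stay ahead cumulatively after 10 cycles
(4.59 vs 4.12 SD), while annualized relative gains fall from >6 %/yr as
additive variance is consumed and prediction accuracy collapses once the
marker panel approaches fixation. The same grid with `contexts=("budget",)`
reverses the ordering (small progenies with many crosses win). A CLI wraps
the same calls: `gainsim run-grid --help`, `gainsim summarize records.csv`.

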