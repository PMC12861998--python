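# Methods

`gainsim` simulates recurrent genomic selection (GS) in a self-pollinated,
rice-like crop and measures how progeny size, number of crosses, epistasis,
and an F2 budget cap shape long-term genetic gain. This note documents the
model, its calibrations, the numerical choices, and what the desk-scale runs
do and do not demonstrate.

## Genome and founders

The genome is 12 chromosomes of 100 cM each. A fixed panel of biallelic
segregating sites (1644 at full scale) is allocated to chromosomes
proportionally to map length and placed on a uniform cM grid; 30 QTNs and 45
SNPs per chromosome are assigned to disjoint sites (SNPs evenly spaced, QTNs
drawn at random from the remainder). Only these sites are tracked — the rest
of the genome is assumed monomorphic or irrelevant to the trait and markers.

Founders are 1000 (full scale) fully homozygous pure lines: single haplotypes
sampled from a per-chromosome neutral coalescent and doubled, as for doubled
haploids or fully inbred landraces. The coalescent (msprime, recombination
rate 0.01/cM, continuous coordinates) uses a generic-crop demography — recent
effective size Ne = 100 with stepwise ancestral expansion (5·Ne at 4Ne·0.25
generations, up to 1000·Ne in the distant past). The recent bottleneck gives
the strong short-range LD typical of selfing crops; the ancestral expansion
supplies an excess of rare variants. Each map locus receives exactly one
mutation, dropped on a branch of the local genealogy chosen proportionally to
branch length: allele frequencies then follow the coalescent site-frequency
spectrum, neighbouring loci share genealogies (realistic LD decay), and every
locus is guaranteed polymorphic among the sampled haplotypes. A constant-size
model is available via `coalescent_params={"model": "constant"}`.

## Trait architecture and calibration

The true genetic value is additive plus pairwise additive×additive epistasis
over QTN dosages coded −1/0/1 and centered at the founder mean:

    G_i = Σ_k a_k x_ik + Σ_(k,l) a_kl x_ik x_il

Additive effects are standard normal by default (a gamma(1,1)-magnitude,
random-sign option is exposed; all effects are rescaled afterwards, so the
choice only affects effect-size skew). Epistatic pairs are disjoint random
QTN pairs — one interaction per QTN, 180 pairs at full scale — the simplest
topology consistent with a purely additive×additive model.

Calibration, performed once on the founder population and then frozen:

1. epistatic effects are scaled so Var(epistatic)/Var(additive) equals the
   requested ratio (0, 0.5, 1.0) exactly;
2. all effects are rescaled so founder Var(G) = 1, and the founder mean of
   the epistatic term is absorbed into an offset so mean(G) = 0 — responses
   are therefore in founder genetic-SD units;
3. σ_e² = (1 − H²)/H² with H² = 0.63, so founder broad-sense heritability is
   0.63; σ_e² is held constant in every later generation and cycle (realized
   heritability therefore declines as genetic variance is consumed).

The ratio and H² targets refer to the realized founder sample, not a
theoretical equilibrium population.

## Reproduction

Meiosis follows the Haldane model: per chromosome, crossover count ~
Poisson(map length in Morgans), crossover positions uniform, no interference;
the transmitted haplotype at a locus is the starting haplotype flipped once
per crossover to its left. Selfing uses single-seed descent (one selfed
offspring per line per generation). A cross between two (nearly) homozygous
parents yields a single F1 genotype, which is selfed to produce the F2
family; modelling the F1 explicitly is what creates within-family segregation
in F2, the raw material of within-family selection.

## Breeding program

**Burn-in (15 years, 3 cycles).** 160 random crosses (F2 families of 100);
a random candidate pool of lines is advanced F2→F5 by single-seed descent,
the pool is phenotyped at F5 and the best 40 become the next cycle's parents
(an optional phenotypic culling at F2 is exposed but off by default). The
published report pins the post-burn-in baseline implicitly: its cumulative
(R) and annualized (R %/yr) responses satisfy Ḡ0 = 2R/R%yr ≈ 2.4–2.5 founder
SD for every no/moderate-epistasis scenario (≈2.1–2.2 under high epistasis).
The candidate pool size (default 150) was calibrated once against that
implied baseline and frozen; truncating the full 16000-line census instead
would triple the burn-in gain and bears no resemblance to what a pedigree
program can phenotype at F5.

**GS cycles (5 years each, 10 cycles).** 40 parents → crosses (40 in the
theoretical context; 4000/progeny-size in the budget context, i.e. 160×25,
80×50, 40×100, 20×200) → F2. A random 20% of the census is the *test* group,
selfed to F5 and phenotyped; the two-kernel GBLUP is fitted on the test group
with F2 marker genotypes (markers are taken where GS acts). The other 80%
(*shelf*) is predicted at F2 by kriging through the test–shelf kinship
blocks; the 32 best shelf individuals on predicted value (80% of the 40
parents) are advanced to F5 and joined by the 8 best test individuals on F5
phenotype; all 40 are selfed once to F6 and become the next parents. The best
F6 line on phenotype is recorded (true G logged). Parent pairs are drawn
without replacement when 2·crosses ≤ parents, otherwise uniformly with
replacement excluding self-pairs.

Prediction accuracy ρ is evaluated on the shelf — the set where predictions
actually drive selection — as the Pearson correlation between projected
predictions and true F2 genetic values. Training uses only the current
cycle's test set (no multi-cycle training-set accumulation).

## GBLUP and REML

G_a = MMᵀ/s with M the union-centered marker matrix and s = tr(MMᵀ)/n, so
mean(diag(G_a)) = 1 (the classical 2Σp_kq_k denominator is available; kernel
scale is absorbed by σ_a², leaving the likelihood unchanged). G_aa′ is the
Hadamard square of G_a normalized by tr/n. Centering and both trace
normalizers are computed on the full F2 census (test ∪ shelf) and the needed
blocks are materialized directly, avoiding the full census×census matrix.

REML maximizes the restricted likelihood of the intercept model by
Newton–Raphson on log-variance parameters (non-negativity by
reparameterization), with the observed-information step replaced by Fisher
scoring when it is not a descent direction, step halving, and components
clamped at 1e−8·Var(y); convergence is |Δ log-restricted-likelihood| < 1e−6
(max 80 iterations; non-convergence flags the result). BLUPs are
σ_i²·K_i·Py at the optimum; shelf projection uses per-component kernels with
a pseudo-inverse (relative cutoff 1e−8). Tests verify the optimizer against
a brute-force likelihood grid, Henderson's mixed-model equations, the
balanced one-way closed form, and the joint-Gaussian conditional-mean
identity for the projection.

## Scenario grid, seeding, scale

The full factorial is context {theoretical, budget} × size {25,50,100,200} ×
epistasis {0, 0.5, 1.0}. Within a replicate, founders are shared across
epistasis levels and the burn-in base (per epistasis level) is reused across
all sizes and contexts, so size contrasts are within-base comparisons. All
randomness derives from one master seed via `SeedSequence` spawn keys
(distinct, reproducible, order-independent streams per replicate × scenario).

Two presets:

* `full` — the study design: 1000 founders, 1644 loci (360 QTN/540 SNP),
  100 replicates, full training sets.
* `reduced` — the desk-scale configuration used by the test suite and the
  acceptance script: 300 founders, 600 loci (120 QTN/180 SNP), 10–20
  replicates, and the GBLUP training set capped at a random 300-individual
  subset of the test group (a genotyping-budget choice). The scheme geometry
  — cross numbers, census sizes, the 4000-F2 cap, selection counts — is kept
  at full scale, so every selection intensity matches the study design; an
  earlier candidate that scaled cross numbers instead was discarded because
  it compresses the selection-intensity contrast between progeny sizes.

## What the desk-scale runs show — and known limitations

Passing tests at the reduced preset demonstrate the mechanics (calibration,
Mendelian genetics, REML/kriging correctness, scheme accounting, seeding) and
the budget-context design conclusion: under a fixed F2 cap, small
progenies with many crosses outperform 20×200 allocations. Two desk-scale
effects should be kept in mind when comparing magnitudes:

* Absolute responses run above study-scale expectations. The burn-in
  calibration fixes the baseline mean, not the genetic variance remaining
  after burn-in; with unspecified burn-in intensities, desk-scale runs retain
  more usable variance and keep gaining for more cycles.
* The training-set cap (300) largely removes the training-set-size →
  accuracy channel: test groups of 400–1600 all train on similar subsets, so
  prediction accuracy — and with it much of the progeny-size effect in the
  unconstrained context — varies far less across sizes than with full
  training sets. The sparser desk-scale marker panel (15 SNPs/chromosome)
  additionally weakens within-family prediction, which is exactly what large
  families exploit. The theoretical-context size ordering is therefore much
  flatter at desk scale than at full scale; running the `full` preset
  restores both channels at ~50–100× the compute.

Not modelled: dominance and higher-order epistasis, genotype×environment and
epistasis×environment interaction, genotyping error, multi-environment
trials, cost accounting beyond the F2 cap, overlapping cycles, and
multi-cycle training-set updating (a config extension hook exists for the
latter's absence to be revisited).
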