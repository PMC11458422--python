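# Methods

## The problem

In a two-way terminal crossbreeding program, purebred sires of a paternal
line (A) are mated to dams of a maternal line (B); the commercial product
is the F1. Selection decisions, however, are taken inside the purebred
lines, usually from purebred data only. Whether that works depends on the
additive genetic correlation between purebred and crossbred performance,

    r_pc = sigma_A(PB,CB) / (sigma_A(PB) * sigma_A(CB)),

which drops below 1 under genotype-by-genotype interaction, G×E, and trait
incompatibilities. This package simulates the whole design forward in time,
injects a controlled r_pc into the QTL effects, and asks which evaluation
model and which genotyping strategy best predict a sire's crossbred progeny
performance at each r_pc level.

## Simulation model

**Genome.** Biallelic loci on a sex-free autosomal map (26 × 131.6 cM at
full scale; 4 × 100 cM on the desk profile). Gametes follow a Haldane model:
crossover counts Poisson in map length, positions uniform, no interference.
Internally, gamete sampling uses the equivalent two-state Markov chain over
loci whose switch probabilities are the Haldane recombination fractions of
the inter-locus distances — exact at locus resolution and fully
vectorizable. Mutation is a recurrent allele flip at 2.5e-5 per locus per
gamete. Founder allele frequencies are i.i.d. uniform on 0.5 ± 0.3, after
which 300–3,000 generations of drift establish mutation–drift LD; starting
from intermediate frequencies reaches equilibrium LD far faster than
starting monomorphic.

**Population design.** A historical population follows a three-phase size
trajectory (constant, linear decline, constant). Two breeds are founded by
random samples from its last generation, expanded by random mating with
five progeny per dam, bottlenecked a second time into the "recent"
populations whose generation 0 is the pedigree base (parents unknown), and
then bred for ten generations with truncation selection on within-breed
pedigree-BLUP EBVs: 50% of sires and 20% of dams replaced per cycle,
culling by age (cap four breeding cycles) before EBV, one random sire per
litter. F1 cohorts AB1–AB3 are produced from breed-A sires × breed-B dams
of generations 8, 9, 10.

**Marker/QTL panel.** A surplus of candidate loci is simulated; at breed
founding, loci with pooled-founder MAF < 0.05 are dropped and the final
markers and QTL are drawn disjointly from the survivors. Filtering on the
pooled A∪B founders keeps both breeds segregating.

**Trait.** Per QTL the purebred/crossbred substitution-effect pair is
bivariate normal with unit variances and correlation r_pc, built from two
shared standard-normal vectors u1, u2 as alpha_pb = u1 and
alpha_cb = r·u1 + sqrt(1−r²)·u2, then rescaled by one common factor so that
Var(TBV_pb) over the base generation equals sigma²_u = 1. An optional
composition layer multiplies both members of a pair by a shared
Gamma(0.4, 1.66) magnitude and a random sign (`use_gamma_magnitude`),
giving a realistic heavy-tailed effect-size distribution; it is off by
default because the squared-Gamma weights reduce the effective number of
QTL for the realized correlation by a factor of ~36, making the realized
r_pc of a single draw extremely noisy. The standalone selection trait
(used when no effect vector is supplied) draws signed Gamma(0.4, 1.66)
effects.

Phenotype = mu + breed + sex + generation + TBV + N(0, sigma²_e), with
h² = 0.3 (so sigma²_e = 7/3) and fixed-effect levels drawn once per world
from N(0, 0.25·sigma²_u) — large enough to exercise fixed-effect
estimation, small enough not to dominate. Purebreds express TBV_pb,
crossbreds TBV_cb. The purebred records generated during the selection
phase are the purebred training records of the evaluation — one data set
drives both, so the selection history is consistent with the evaluated
trait.

**Common random numbers.** Within a replicate, all r_pc levels share the
pedigree, genotypes, u1/u2, fixed-effect values and residual draws; only
alpha_cb changes with r. The study's estimand is a *contrast across r_pc
levels*, and CRN removes between-level Monte-Carlo noise from that
contrast; purebred records are literally identical across levels.

## Evaluation models

All models solve Henderson's mixed model equations for
y = Xb + Zu + e with lambda = sigma²_e/sigma²_u fixed at the simulated
truth (REML is available — see below — but truth isolates
model-structure differences from estimation noise). Fixed effects: breed,
sex, generation, treatment-coded with aliased columns dropped (breed and
cohort generation are confounded for crossbreds; dropping aliased columns
is equivalent to contemporary-group coding).

* **BLUP-UPG** — pedigree-only; the unknown parents of generation 0 map to
  one unknown-parent group per breed via the Quaas–Pollak augmentation of
  A⁻¹. Inbreeding enters through Meuwissen–Luo coefficients.
* **ssGBLUP** — H⁻¹ = A⁻¹ + [0 0; 0 Gb⁻¹ − A22⁻¹] where
  G = ZZ′/2Σp(1−p) (VanRaden, observed frequencies of the genotyped set)
  and Gb = 0.95·G + 0.05·A22. Blending is applied in both genomic models
  for invertibility.
* **ssGBLUP-MF** — two metafounders (one per breed) act as sire and dam of
  all base animals; their relationship matrix Γ is estimated as 8 × the
  (co)variance across loci of the breeds' base allele frequencies, floored
  to positive definite. A_Γ⁻¹ comes from Henderson's rules with
  generalized inbreeding (founder diagonal γ_bb); the genomic matrix uses
  fixed 0.5 frequencies (Z = counts − 1, denominator m/2), the scale
  compatible with the Γ base; H_Γ⁻¹ uses τ = ω = 1 and the same 0.95/0.05
  blend.

Genotyping scenarios mask which populations contribute genotypes:
SC1 = {A, B, F1}, SC2 = {A, B}, SC3 = {A}, SC4 = {B}. The genotype pools
are all breeding sires of each breed, the crossing sires (A), a sample of
crossing dams (B), and samples of AB1/AB2 (used by SC1 only). Training
phenotypes are the purebred records of all generations, plus AB1∪AB2
crossbred records in SC1 cells. AB3 is the validation cohort: its
phenotypes never enter training, and its genotypes are not collected.

## Scoring

* **Accuracy** — the Pearson correlation, weighted by the progeny-mean
  reliability n/(n+k) with k = (4−h²)/h², between breed-A sire EBVs and the
  mean fixed-effect-adjusted phenotype (y − Xb̂, using the cell's own b̂) of
  their AB3 progeny. An unweighted option exists; the weighting does not
  change the qualitative ordering.
* **Dispersion b1** — the OLS slope of TBV on EBV over the validation
  sires; 1 is scale-unbiased, >1 under-prediction. The reported b1 uses the
  sires' purebred-scale TBV — the scale the evaluation actually estimates —
  because with crossbred phenotypes excluded from training the
  crossbred-scale slope equals ≈ r_pc by construction (the EBV contains
  only the u1 component, so cov(TBV_cb, û) ≈ r·var(û)); that mechanical
  attenuation is reported separately as `b1_cb` rather than being read as
  mis-calibration.
* **F_ST** — Hudson's estimator as a ratio of sums across loci (low bias at
  small samples); Weir–Cockerham (allele-based) by flag.
* **PCA** — eigendecomposition of centered allele counts; the F1 cluster
  should sit between the parental clusters on PC1.

## Variance-component estimation

`estimate_variances(method="reml")` maximizes the exact restricted
log-likelihood, profiled to one dimension: for a candidate heritability,
lambda = (1−h²)/h², the MME are solved once, sigma²_e is profiled in
closed form, and −2·logL_R = (n−p)·log σ̂²_e − q·log λ + log|C_λ| up to a
constant, with log|C_λ| from a sparse LU factorization. A bounded scalar
search over h² converges in ~25 evaluations. This replaces an EM
iteration, which would need traces of the inverse coefficient matrix
(O(n³) per step at realistic sizes); the profile likelihood is exact and
verified against a dense multivariate-normal REML oracle in the tests.
The study default remains `method="true"`.

## Numerical choices

* Sparse inverses are assembled from vectorized Henderson rules; the
  Meuwissen–Luo diagonal computation (generalized to a correlated founder
  block for metafounders) is a numba kernel, validated against dense
  tabular inverses to 1e-8 on random pedigrees.
* A22 / A_Γ22 come from Colleau's indirect method — two triangular solves
  with (I−P) per column block — never from a dense A.
* Genotyped-block inversions use dense Cholesky (panels ≤ a few thousand);
  no APY-style approximation.
* MME solving: sparse LU for the study sizes, with diagonally
  preconditioned conjugate gradients (tol 1e-8, cap 5,000 iterations) as
  the large-system option; the two agree to 1e-6 on kilo-equation systems.
* Monomorphic markers inside a scenario's genotype pool are excluded from
  that pool's VanRaden G (its denominator requires segregation); the
  0.5-frequency G keeps all loci.
* Seeds: replicate i uses `SeedSequence([base_seed, i])`; a study is
  bit-reproducible end to end for a given base seed.

## Scale profiles

The full design (Table-scale: 50K markers, 500 QTL, 5,000→2,000 historical,
breeds 50♂/500♀ expanded 200 generations, recent 100♂/1,000♀) runs for
hours. The desk profile keeps the design's shape at minutes-scale: 2,000
markers, 100 QTL on 4×100 cM, historical 300→220 over 300 generations,
breeds founded from 10♂/100♀ (sampled independently per breed — a final
generation of 220 cannot supply disjoint founder sets of that size),
expansion 30 generations capped at 500, recent 20♂/200♀, crossing 100
sires × 4 dams × 5 progeny per cohort. Tests and the acceptance script use
the desk profile with 5 replicates.

## What the desk profile does and does not show

Scaling down shrinks effective population sizes, so drift-driven
quantities are larger than at full scale: desk F_ST between breeds is
~0.2 (full design: a few hundredths), PC1/PC2 variance fractions are
correspondingly larger, and per-replicate realized r_pc at 100 QTL
scatters ±0.1 around its target. The desk runs therefore support
*qualitative* conclusions — monotone accuracy in r_pc, model orderings,
calibrated dispersion — not the printed full-scale magnitudes. The
generator also idealizes real data: discrete generations, no missing
pedigree beyond generation 0, no genotyping errors, single trait, no
dominance or epistasis (r_pc deviations are induced purely through the
effect correlation), and equal-length chromosomes.

## Known limitations

* The metafounder model reuses the purebred sigma²_u; the small variance
  rescaling implied by a Γ base (≈ 1 + γ̄/2 − ...) is not applied.
* Γ is computed from the simulator's true base frequencies; estimating it
  from genotyped descendants is stubbed in the configuration but not
  implemented.
* The Weir–Cockerham F_ST variant treats alleles as the sampling unit
  (no observed-heterozygosity term); Hudson is the default everywhere.
* Selection-phase BLUP uses all records accumulated so far (the
  alternative — current generation only — is supported by filtering the
  record set, not by a switch).
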