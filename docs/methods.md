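# Methods

## Model

For a single-record trait the full animal model is

    y = Xb + Z u + Z_m m + S q + Z ξ + e,

with u the direct additive genetic effect (u ~ N(0, Aσ²u) or N(0, Hσ²u)),
m the maternal additive effect (optionally correlated with u through the
2×2 block [[σ²u, σu,m],[σu,m, σ²m]] ⊗ A), q the common-litter environment
(iid), ξ the transgenerational epigenetic effect (ξ ~ N(0, Λσ²ξ)), and e the
residual.  Repeated-record traits replace m and q with a permanent
environment effect pe (iid per animal).  All effects are assumed mutually
independent, epigenetic variance is assumed constant across generations and
sexes, and the phenotypic variance is the sum of the fitted components with
the direct–maternal covariance counted once.

### The epigenetic relationship matrix

Λ is generated by ξᵢ = λ(ξ_s + ξ_d) + εᵢ with Var(εᵢ) = dᵢσ²ξ and
λ = 0.5(1 − ν).  dᵢ is fixed at 1−2λ² / 1−λ² / 1 by the number of known
parents, regardless of the epigenetic relatedness of the mates.  This is the
simple rule of the source construction: it keeps the factorization
Λ = (I−P)⁻¹D(I−P)⁻ᵀ exact, so the long-format inverse
Λ⁻¹ = (I−P)ᵀD⁻¹(I−P) agrees with the numerically inverted dense recursion to
machine precision (the test suite verifies < 1e−8 over random pedigrees and
the whole grid).  The price is that Λᵢᵢ can slightly exceed 1 when mates are
epigenetically related.  At λ = 0.5 the rules coincide with the non-inbred
A⁻¹ rules; at λ = 0, Λ = I.  λ = 0 is allowed by the library but excluded
from the default model grid (0.05…0.45 by 0.05), because an iid ξ is not
identifiable against the residual for single-record traits.

### Relationship machinery

A⁻¹ uses Henderson's rules with inbreeding from the Meuwissen–Luo
algorithm; the tabular A is kept for oracles, A22 extraction and REML.
The single-step H⁻¹ adds τ(αG + βA22)⁻¹ − ωA22⁻¹ on the genotyped block
with defaults α = 0.95, β = 0.05, τ = ω = 1.  G is VanRaden's method 1 with
observed allele frequencies and missing genotypes imputed to 2p — the
conventional choices where the construction leaves them open.

## Inference

### Gibbs sampler

Location effects are sampled equation-by-equation from their normal full
conditionals over Henderson's mixed-model equations (single-site Gibbs; the
sweep is numba-compiled, the penalty part of the LHS is rebuilt each round
from per-component data vectors mapped onto a shared sparsity pattern).
Variances use flat (improper, bounded at zero) priors: each full conditional
is a scaled inverse chi-square with degrees of freedom n_levels − 2 and scale
a′K⁻¹a; the direct–maternal block is drawn from an inverse-Wishart with
df = n − 3 and scale matrix of the A⁻¹ quadratic forms; the residual uses
e′e with df = n_records − 2.  Heritability ratios are computed **per sample**
(not as ratios of posterior means), so posterior SDs of h² reflect the joint
uncertainty.  Starting values are an equal split of the phenotypic variance
over the fitted components; with flat priors the chain forgets them after
burn-in.

DIC uses the conditional (location-parameter) deviance
D(θ) = −2 Σ log N(yᵢ | ŷᵢ(θ), σ²e), DIC = 2·mean(D) − D(posterior means) —
the convention of the Gibbs-sampling software family this workflow mirrors;
DIC flavours differ, so the choice is stated explicitly.  Convergence is
summarized by the Geweke z (first 10% vs last 50% of the chain, spectral
variance at frequency zero via Geyer's initial-positive-sequence estimator)
with a 5% two-sided threshold, shortest-interval HPDs, and pairwise sample
correlations with a 5% significance mask.  A chain-doubling helper rerun
doubles size and burn-in while any |z| ≥ 1.96.

### AI-REML

For model building (choosing random-effect sets by AIC) the restricted
likelihood is maximized by average-information Newton steps with step-halving
into the parameter space, an EM-style fallback when the AI matrix is
singular, and zero-boundary pinning.  It operates on the dense phenotypic
covariance V = Σ σ²ₖ ZₖKₖZₖ′ + σ²eI, which is exact and simple but limits it
to a few thousand records — adequate for its role here; the Gibbs sampler is
the production estimator.  AIC = −2 logL_R + 2·(free covariance parameters).

### LR validation

Focal animals default to the youngest phenotyped cohort.  Accuracy uses the
square-root convention √(cov(EBV_w, EBV_p)/((1−F̄)σ̂²u)) so that it estimates
the correlation between partial-data EBV and true breeding value; the
squared variant is one line away in `lr_metrics`.  F̄ is the pedigree mean
inbreeding of the focal animals (genomic inbreeding can be substituted);
σ̂²u comes from the whole-data fit of the same model.  Bias is
mean(EBV_p) − mean(EBV_w) in trait units; dispersion is the regression
slope minus one.  A negative whole/partial covariance is reported as
accuracy 0 with a warning rather than a complex number.

## Synthetic data

The generator emulates a nucleus pig herd: discrete non-overlapping
generations, random mating (each sire serving up to `dams_per_sire` dams,
each dam producing `litters_per_dam` litters of truncated-Poisson size on
[3, 20]), alternating-sex founders, and an optional target generation size
that holds the population roughly stationary.  Direct and maternal effects
flow jointly through the pedigree with Mendelian sampling variance
dᵢ·G0 shrunk by parental inbreeding (maternal values are drawn for all
animals, expressed only through dams).  Epigenetic effects follow the ξ
recursion exactly; litter and permanent-environment effects are iid;
genotypes are gene-dropped from founder alleles at uniform frequencies.
Systematic effects (sex, parity, year-month-farm contemporary groups, one
linear covariate) exercise the design-matrix code.  One root seed feeds
per-component substreams, so datasets regenerate bit-for-bit.

Defaults are the recovery study conditions: 100 founders, 5 generations of
~600 offspring (~2,500 animals), single-record trait on a unit phenotypic
scale with h²u = 0.10, q² = 0.15, h²ξ = 0.30 at reset ν = 0.9 (λ = 0.05).
The repeated-record preset mirrors litter-size traits (σ²u = 0.55,
σ²pe = 0.60, σ²ξ = 0.50, σ²e = 9.8, three parities per sow).

What the generator does **not** emulate: selection (mating is random, real
nucleus herds select), overlapping generations, cross-fostering,
genotype-dependent epigenetic effects, and non-Gaussian trait distributions.
Passing recovery tests therefore demonstrates correctness of the machinery
under the model's own assumptions, not robustness to their violation in
field data.

## Numerical choices and scale

- The MME are solved by sparse LU with a least-norm LSMR fallback for
  rank-deficient fixed blocks (relative residual ≤ 1e−8 target).
- Identifiability: at λ = 0.05 with single records, σ²ξ is separated from
  σ²e only by weak covariances among relatives.  Posteriors for h²ξ are
  accordingly diffuse and strongly negatively correlated with σ²e; when the
  true σ²ξ is zero the posterior piles against the zero boundary (lower HPD
  bound at 0) rather than collapsing to a point.  For repeated records the
  same trade-off runs against σ²pe.  Long chains are the remedy; the
  convergence summaries make slow mixing visible.
- Test and acceptance runs use chains of 50,000 (recovery) down to 8,000
  (model-comparison sweeps) samples and populations of ~800–2,500 animals —
  sizes chosen so the whole validation cycle runs on a laptop while leaving
  the recovery properties clearly resolved.
- Phenotype QC computes the mean and SD once, before filtering, with a
  closed ±3.5 SD interval; the 4-generation completeness rule is a
  configurable threshold on the MacCluer-style index (default 0.25 at depth
  4 ≈ both parents known), since "complete" is not standardized.
- Undersized contemporary groups (and other fixed-effect levels) drop their
  records rather than merging levels.
- Fixed effects are dummy-coded with a dropped reference level; remaining
  rank deficiencies resolve through the least-norm solver convention.

## Known limitations

- Single-trait models only; no threshold/categorical machinery.
- AI-REML is dense-V and not intended for large records counts.
- The LR dispersion statistic has large sampling variance when EBV accuracy
  is low (e.g. h²u ≈ 0.10); it is unbiased across replicates but individual
  replicates scatter by ±0.2 or more — judge dispersion on replicate means.
- No unknown-parent groups or metafounders; unknown parents map to one base
  population.
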