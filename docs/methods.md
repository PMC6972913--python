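# Methods

## Models

### Region-wise Bayesian regression (BayesN0)

Phenotypes of genotyped animals for two traits, L and H, are modeled with
one general mean per trait and all markers as random effects:
`y_t = 1 mu_t + M alpha_t + e_t`. Residual vectors stack across traits with
`e ~ N(0, R0 ⊗ I)` (every recorded animal has both traits, so the marker
design is shared). Markers are partitioned into contiguous regions and all
SNPs in region `s` share the 2×2 effect (co)variance `B_s`; the prior is
`alpha_sj | B_s ~ N(0, B_s)` with conjugate inverse-Wishart hyperpriors on
`B_s` and `R0`. Sampling is a systematic Gibbs scan per cycle —
mean(s) → each SNP effect in map order → every `B_s` → `R0` — with the
residual vector updated incrementally after every effect draw (the scan
order between blocks is a free choice; any fixed order is a valid scan).
Each SNP update solves the 2×2 system
`(m_j'm_j) R0⁻¹ + B_s⁻¹` exactly. Region size one gives BayesA behavior
(each `B_s` conditional gains a single degree of freedom, so the prior
stays influential no matter how much data there is); a single whole-genome
region is the SNPBLUP/GBLUP-equivalent model; intermediate sizes are the
interesting regime.

Single-trait analyses are the exact scalar specialization: all covariance
objects become 1×1 and the inverse-Wishart degenerates to the scaled
inverse-chi-square with the matching mean, so priors are consistent
between single- and multi-trait runs.

### Single-step extension (ssBayesN0)

Non-genotyped animals contribute phenotypes through their pedigree-imputed
genotypes `M̂_n = A_ng A_gg⁻¹ M_g` (computed with a symmetric solve, never
an explicit inverse; raw allele counts are imputed first and both blocks
are then centered by the same `2 p_j`, with `p_j` from genotyped animals).
Per trait the fixed design gains a genotyped-mean contrast column
(`-A_ng A_gg⁻¹ 1` on non-genotyped records, `-1` on genotyped records),
and every non-genotyped pedigree animal gets an imputation residual with
prior `eps ~ N(0, G0 ⊗ A)` — the residual covers *all* non-genotyped
animals, not only recorded ones, because the breeding-value predictor for
unrecorded ancestors needs it. Its full conditional is the multivariate
normal with precision `U'R⁻¹U + G0⁻¹ ⊗ A⁻ⁿⁿ`, where `A⁻ⁿⁿ` is the
non-genotyped block of the sparse pedigree-inverse. Two exact update
strategies are implemented and verified against each other: a joint draw
via dense Cholesky of the precision (used when the number of non-genotyped
animals is ≤ 150) and a single-site scan exploiting the sparsity of
`A⁻ⁿⁿ` (used above that; same stationary distribution, cheaper per cycle).
When every animal is genotyped the contrast column is collinear with the
intercept and is dropped; the model then reduces exactly to BayesN0.

### Plug-in single-step SNPBLUP

With `B_s`, `R0`, `G0` fixed (posterior means from a BayesN0 chain —
"ssSNPB1" — or a ssBayesN0 chain — "ssSNPB2"), the posterior mean of all
location effects solves a symmetric linear system. The coefficient
operator is applied matrix-free (X, W, U and the prior blocks applied in
sequence; `B⁻¹` is block-diagonal with each SNP's 2×2 inverse of its
region's matrix) and solved by conjugate gradients with Jacobi (diagonal)
preconditioning; the diagonal is assembled analytically. Convergence is
declared on the plain relative residual `‖b − Cx‖/‖b‖ ≤ tol` (default
1e-12) — the preconditioned norm differs only by a bounded factor and the
plain residual is directly checkable. For the ssSNPB1 route the genetic
covariance `G0` is the across-cycle mean of the empirical (co)variance of
breeding values `M alpha` from the source chain; for ssSNPB2 it is the
posterior mean of the sampled `G0`.

## Priors and hyperparameters

Base (co)variances `G̃0`, `R̃0` (or single-trait `σ̃²_g`, `σ̃²_e`) come from
a SNP-level ridge-regression fit: the package's own sampler with one
whole-genome region under weakly informative priors anchored at half the
phenotypic variance, with the SNP-level variance scaled to the genetic
level by `Σ 2p_j(1−p_j)`. Hyperparameters are then set so every prior mean
equals its base estimate: `V_B = (v−3) G̃0 / Σ2p(1−p)`, `V_R = (v−3) R̃0`,
`V_G = (v−3) G̃0` with `v = 5` for two traits; the implied marginal for
each diagonal is a scaled inverse-chi-square with 4 degrees of freedom and
scale `σ̃²/2`, and the single-trait priors use exactly that distribution
(df 4, scale `σ̃²(df−2)/df`), so single- and multi-trait priors agree in
mean and in family. Inverse-Wishart convention throughout:
`Σ ~ IW(ν, V)` means `Σ⁻¹ ~ Wishart(ν, V⁻¹)` and `E[Σ] = V/(ν − p − 1)`;
2×2 draws use a vectorized Bartlett construction.

Chain defaults are desk-scale — 5,000 cycles, 2,000 burn-in, thinning 10 —
with the full-scale settings (50,000 / 30,000 / 10, or 70,000 / 50,000 for
convergence checking) available through `ChainOptions`/config. The point
estimate of every parameter is its posterior mean. Divergence (a
non-finite residual) aborts with the cycle index; residuals are
recomputed exactly every 200 cycles to cap floating-point drift.

## Simulator

The generator emulates the study design the analysis modules are meant
for: a dairy-cattle-like population with genotyped males, partially
genotyped females and a genotyped, unphenotyped validation generation.

* **Founders.** Allele frequencies are Beta-distributed (default uniform,
  clipped to [0.03, 0.97]); haplotypes are first-order Markov chains along
  each chromosome with neighbor correlation `ld_rho` (default 0.7, typical
  of adjacent markers on a mid-density cattle panel). For binary alleles
  the achievable correlation between loci of unequal frequency is capped
  at the Fréchet bound, so the realized mean neighbor correlation under
  heterogeneous frequencies sits below the nominal value; with
  near-equal frequencies it matches it. This is the one deliberately
  synthetic ingredient — it stands in for real haplotype panels and
  reproduces LD decay only as a first-order chain, not long-range
  haplotype structure, so passing tests say nothing about LD-dependent
  fine-mapping behavior on real data.
* **Mating.** Each generation keeps 200 males and 2,000 females (defaults;
  any 1:10 ratio allowed). Dams are partitioned randomly, ten per sire,
  one offspring each; every sire additionally repeats one mating with one
  of his ten dams chosen uniformly (the repeat rule is one documented
  reading of the design), giving 2,200 offspring. Gametes recombine under
  the Haldane model, one Morgan per chromosome by default. No selection,
  no dominance, no sex chromosomes.
* **QTL.** 200 QTL (default) are chosen at random subject to a mean minor
  allele frequency of 0.15 ± 0.005 by greedy random swaps; the swap loop
  aims at a band one fifth of the tolerance so the achieved mean is
  centered rather than stopping at the tolerance edge. QTL are removed
  from the analysis marker set. 82% are pleiotropic (floor rounding), the
  remainder split evenly between trait-L-only and trait-H-only (odd
  leftover to L).
* **Effects.** Scenario G9: pleiotropic magnitudes are Gamma(0.4, 1.66)
  pairs (shape/scale reading) with raw-scale Pearson correlation 0.9 via a
  Gaussian copula whose latent correlation (0.9266) is calibrated by
  Gauss–Hermite quadrature and Brent's method; each pair gets a common
  random sign, and for a 22% subset the sign of one random trait is
  switched. Scenario N5: standard bivariate normal with correlation 0.5.
  Both scenarios yield founder-generation genetic correlations of about
  0.45 (heavy-tailed G9 fluctuates strongly across replicates — SD ≈ 0.29
  at the desk scale of 100 QTL — which is why calibration checks average
  many replicates).
* **Phenotypes.** `g = M_qtl γ`; residual variances are set from the
  *realized* founder genetic variance, `σ²_e = var(g) (1−h²)/h²` with
  h² = 0.1 and 0.4, and residuals are drawn independently per trait (the
  analysis models still estimate a full `R0`).
* **Masking.** Training generations: all males genotyped (no phenotypes),
  500 random females genotyped + phenotyped, the remaining 1,500 females
  phenotyped only; validation generation: 500 random animals genotyped,
  none phenotyped; earlier generations contribute pedigree only. All
  counts are configurable and scale down proportionally.

## Pedigree algebra

`A` is built dense by the tabular method (row-vectorized; a warning guards
allocations beyond 8,000 animals). `A⁻¹` is assembled sparse by
Henderson's rules with Mendelian-sampling variances from inbreeding
coefficients computed with the Meuwissen–Luo ancestor recursion (a numba
kernel); `A⁻ⁿⁿ` is read off as the (n,n) block of that sparse inverse.
Animals with unknown parents are treated as unrelated founders.

## Numerical choices and degenerate inputs

* Markers monomorphic among genotyped animals are dropped before analysis
  (they carry no information and break the centering convention).
* Small-matrix (1×1/2×2) inversions and Cholesky factors are closed-form
  and vectorized across regions; all stored covariance samples are
  checked SPD in tests.
* A rank-deficient fixed-effect design (the genotyped-mean contrast with
  no non-genotyped animals) is handled by sampling in the row space;
  normally the collinear column is dropped at system build time.
* PCG raises an error carrying the best residual when the iteration cap
  is hit; the identity system converges in one iteration.
* Seeds: every stochastic routine takes an explicit seed; pre-generated
  normal draws feed the numba kernels so chains are bit-reproducible.

## Evaluation protocol

Accuracy is the Pearson correlation between true and predicted breeding
values of validation animals; bias is the slope of the regression of true
on predicted values; prediction-error variance is the per-animal variance
(n−1 denominator) of posterior breeding-value samples. Methods are
compared by two-sided paired t-tests, paired across replicates, with a
Bonferroni threshold `alpha / n_pairs` within each comparison family
(trait × animal group by default; within-region-size and within-model
families mirror the two natural tables), and compact letters are assigned
by greedy grouping of the non-significant pairs.

The replicated experiment driver runs desk-scale problem sizes by default
(hundreds of animals, hundreds of markers, thousands of MCMC cycles);
these sizes were chosen so a full replicated comparison runs on a laptop
core in minutes while keeping every qualitative contrast — multi- vs
single-trait, single-step vs genotyped-only, region-size effects —
detectable as a paired tendency across replicates. Directional checks in
the test suite use around a dozen replicates of a configuration with 100
QTL (stabilizing the realized genetic correlation) and a few hundred
validation animals, assessed by one-sided sign tests.

## Known limitations

* Two traits only; the types are written for the bivariate case.
* No variable selection (the region- and SNP-inclusion probabilities of
  the nested partitioned-regression family are fixed at zero here).
* Dense `A`/`A_gg` limit the pedigree size to desk scale; no
  APY-style approximations.
* The founder-haplotype model is synthetic (see above); absolute
  accuracies from the simulator are not comparable to values obtained on
  real haplotype panels, only orderings and calibration quantities are.
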