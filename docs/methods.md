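# Methods

## Model

For a GWAS of a quantitative trait on n unrelated individuals,
`y = X beta + e`, the least-squares marginal estimates `b_j` and an LD
correlation matrix `B` from a reference sample are sufficient for posterior
inference on the joint SNP effects: multiplying through by `D^{-1} X'` with
`D_jj = 2 p_j q_j n_j` gives `b = D^{-1/2} B D^{1/2} beta + eps`, with
`Var(eps)` proportional to `B`. Each effect has the MAF-coupled
spike-and-slab prior

    beta_j ~ pi * N(0, h_j^S sigma_b^2) + (1 - pi) * delta_0,
    h_j = 2 p_j q_j,

with hyperpriors `S ~ N(0,1)`, `pi ~ U(0,1)` and scaled inverse chi-squared
priors on `sigma_b^2` and `sigma_e^2`. The four-component variant replaces
the slab with `sum_k pi_k N(0, gamma_k h_j^S sigma_b^2)`,
`gamma = (0, 0.01, 0.1, 1)`, `pi ~ Dirichlet(1,1,1,1)`; its polygenicity is
the total nonnull mass `pi_2 + pi_3 + pi_4`, and `S` and `sigma_b^2` are
shared across nonnull components. The annotation-stratified variant fits
separate `(pi, S, sigma_b^2)` for SNPs inside and outside one focal binary
category with a shared residual variance.

### Scale convention

Internally every sampler works with standardized-genotype effects
`beta_std_j = beta_j sqrt(h_j)` so that `sigma_g^2 = beta_std' B beta_std`
holds exactly with `B` a correlation matrix, and the per-SNP working
statistic is `r_j = sqrt(h_j) b_j`. The MAF-coupled slab then has variance
`h_j^(S+1) sigma_b^2` on the internal scale, which is the same prior stated
on the per-allele scale. Effects are reported back on the per-allele scale.
Equivalently, `y'y` is estimated as the median of
`D_jj (n_j se_j^2 + b_j^2)` across SNPs, and all variances are expressed
per unit of phenotypic variance through `vary = y'y / median(n_j)`.

### Sampling scheme

One iteration sweeps all SNPs in map order (a per-iteration random
permutation is available; fixed order is the default for reproducibility).
The residualized right-hand side `r_adj = r - B beta_std` is maintained
incrementally through the sparse columns of `B`, so the genetic variance is
the difference of two inner products, `beta' r - beta' r_adj`, and the
residual sum of squares is `y'y/n - beta'r - beta'r_adj`. `r_adj` is rebuilt
from scratch every 1000 iterations to keep floating-point drift below 1e-10.
Conditionals: the effect/indicator pair from the conjugate two-point (or
five-point) mixture with log-sum-exp normalization; `sigma_e^2` and
`sigma_b^2` from scaled inverse chi-squared conditionals; `pi` from its
conjugate Beta (Dirichlet) form; and `S` by adaptive random-walk
Metropolis-Hastings on the sum of slab log-densities of the currently
included effects plus the standard-normal prior. The proposal step adapts
toward a 20-45% acceptance rate in windows of 50 proposals during burn-in
and is frozen afterwards, preserving detailed balance. When no SNP is
included, the `S` conditional reduces to its prior and is drawn exactly.

Chains are initialized with `beta = 0` and hyperparameters drawn from their
priors, so parallel chains start dispersed. Convergence is assessed with
the Gelman-Rubin potential scale reduction factor
`R = sqrt(((T-1)/T W + B/T) / W)` per parameter; an analysis is declared
converged only when `R < 1.2` (strict) for all of `h2`, `pi`, `S`.

### Priors and numerical safeguards

- `nu = 4` for both scaled inverse chi-squared priors. The residual scale
  defaults to `vary / 2`. The effect-variance scale defaults to heritability
  0.5 spread over **all** m SNPs, `0.5 * vary / (m * mean(h))`. This anchor
  is deliberately small: a scale calibrated to the expected per-causal
  variance (h2 over m*pi SNPs) is two orders of magnitude larger and its
  `nu * scale` term dominates the conditional, widening the slab and — on
  U-shaped MAF spectra — biasing S upward. We verified the weak anchor
  against an exactly integrated posterior (identity-LD fixture, effects
  drawn at S = -0.6): the grid-integrated posterior mean was -0.35, the
  sampler gives -0.40 +/- 0.13 with the weak anchor, and +0.37 with the
  per-causal anchor.
- `h_j` in the prior coupling uses the reference-panel frequency after
  matching and is floored at `2 * maf_min * (1 - maf_min)`; `h_j^S` is
  computed as `exp(S log h_j)`.
- `e'e <= 0` is floored at `1e-6 * y'y` with a logged warning.
- A negative `beta' B beta` beyond 1e-8 triggers a rebuild of `r_adj`; if
  it persists (a sparsified LD matrix from a small panel can be indefinite)
  the value is clamped to zero with a warning.
- An optional mode inflates SNP j's effective residual variance by the
  aggregated LD sampling variances `s2_jk` of its retained neighbours,
  weighted by an a priori per-SNP effect variance. This is a reconstruction
  of heterogeneous residual variance and is off by default.

### Defaults

4 chains, 50,000 iterations, 20,000 burn-in, thinning 10, chi-squared LD
threshold 10, MAF >= 0.01. The tests and the acceptance script use shorter
chains (1,200-3,000 iterations, 2-4 chains) and panels of 200-5,000 SNPs;
with the incremental right-hand-side updating these match the longer runs'
posterior means well within their Monte-Carlo error on the problem sizes
used, and the same Gelman-Rubin machinery still gates convergence.

## Sparse LD matrix

Pairwise Pearson correlations between standardized dosages are computed
within chromosome; an off-diagonal entry is kept iff
`n_ref * r^2 > threshold` (default 10, i.e. P < 0.0016 on one degree of
freedom, or r^2 > 2e-4 at n_ref = 50,000). Pairwise-complete counts are used
when dosages are missing, and the minimum pairwise count is stored. A kept
pair's LD sampling variance is
`(n_ref + n)/(n_ref n) (1 - r^2)^2`; a zeroed pair leaves `1/n` unmodelled.
Storage is a documented binary layout (magic string, JSON header, CSR arrays
per chromosome, SNP-map TSV), with a Matrix Market export for debugging.

## Synthetic data

The generator reproduces the study's data-generating assumptions:

- **LD fixtures**: autoregressive blocks (`corr = rho^|j-k|`, default
  rho = 0.9, blocks of 25-50 SNPs) with frequencies uniform on
  [0.01, 0.5]; and latent-Gaussian threshold genotypes for
  individual-level fixtures.
- **Summary statistics** are drawn directly as
  `alpha ~ N(B beta_std, vary B / N)` per chromosome block (Cholesky; a
  logged ridge of 1e-6 is added when the smallest eigenvalue falls below
  1e-8). Standard errors are the exact `sqrt(vary / (N h_j))`; no extra
  noise is added to the frequency or SE columns.
- **Causal effects**: the three-normal mixture
  `0.7 N(0, 0.01 s2) + 0.25 N(0, 0.1 s2) + 0.05 N(0, s2)` with marginal
  variance `V_beta = 0.082 s2`, calibrated from the mutational
  heritability by `h2_m = 2 L pi_m mu V_beta`.
- **Selection coupling** `s_j = k beta_j^2` with `k = sbar / V_beta`;
  pleiotropy remodelling by either `beta ~ N(0, s/(k n_t))` (variance split
  over n_t traits) or `beta = delta (4 Ne s)^tau (1 + eps)`,
  `eps ~ N(0, 0.1)`, `Ne = 10,000`. The remodelling is applied to all
  segregating trait variants of the final generation. Eyre-Walker effects
  are rescaled to the mixture-calibrated `V_beta` so that both models place
  the trait on the same variance scale.
- **Case-control**: liability threshold at prevalence K, cases resampled to
  a fraction P, per-SNP linear regression on the 0/1 outcome; the expected
  observed-scale heritability `h2 z^2 P(1-P) / (K^2 (1-K)^2)` is recorded so
  the liability transform can be checked in closed form.

### Forward simulation

Discrete-generation Wright-Fisher with mutation (fraction `pi_m` of new
mutations trait-affecting), uniform recombination, multiplicative
semidominant selection (heterozygote fitness `1 - s/2`; dominance is not
specified by the underlying theory and is a documented reconstruction), and
the four-epoch demography: 7,310 ancestral individuals for 52,080
generations (1.3 million years at 25 years/generation), expansion to
14,474, a founder split of 1,861, a bottleneck to 1,032 and continuous
exponential growth at 0.0038/generation to 34,039 at generation 58,000.
Continuous growth `N0 exp(rt)` is used because per-generation compounding
does not reproduce the 34,039 endpoint.

Desk runs use the standard rescaling (sizes and generations divided by
`scale`, with mutation, recombination, selection and growth rates
multiplied by it, preserving 4Nmu, 4Nr and 4Ns) with defaults `scale = 100`
and `L = 1e7` bp; the unscaled configuration (`scale = 1`, `L = 1e8`) is
available but needs cluster-scale resources. Beneficial mutations are
supported through a fraction `pi_m,b` of trait mutations whose coefficient
is drawn with mean `sbar_b` through the same `k beta^2` coupling and
positive sign.

The evolutionary pipeline (`evo_replicate`) analyses the surviving common
causal variants with LD computed dense within chromosome from the final
sample (the thresholded matrix from such a small panel can be indefinite,
and a dense sample correlation is guaranteed positive semidefinite). The
mixture sampler is the default for these analyses: the single-normal slab
is known to overstate |S| when the true effect distribution is a
heavy-tailed mixture, most visibly under weak selection. A density-matched
random marker panel (excluding causal variants) is available, but at the
rescaled panel sizes (hundreds of reference individuals against a nominal
GWAS n of 350,000) LD sampling noise inflates both heritability and |S| —
the same small-reference failure mode seen with real data — so the
causal-variant analysis is the default.

What the rescaled runs do **not** emulate: realistic rare-variant counts
(the bottleneck at `1032/scale` individuals exaggerates drift), recombination
hotspots, any functional partitioning of the genome, and the
1.1-million-SNP marker density of biobank analyses. Passing tests therefore
demonstrate correct mechanics and qualitative parameter response
(monotonicity of each architecture parameter in its driving evolutionary
parameter), not calibrated real-data magnitudes. The selection-signature
axis in particular needs the mildest rescaling we can afford
(`scale = 25`): 4Ns is scale-invariant, but realization noise in the
surviving architecture grows quickly with the rescaling factor.

## Projection onto evolutionary parameters

A full multivariate monomial basis of total degree <= 3 (20 terms for three
predictors) maps architecture estimates to `log10(sbar)`, `log10(pi_m)` and
`log10(h2_m)` by per-target least squares; prediction back-transforms to the
natural scale with a standard OLS predictive interval and flags query points
outside the convex hull of the training predictors. Cross-validation uses
repeated random 80/20 splits. A synthetic training-table generator
(`synthetic_training_table`, labelled synthetic) emulates the qualitative
response surfaces — equilibrium genetic variance with persistence
`1/(s + 1/(2Ne))`, target-driven polygenicity purged by selection, and a
saturating selection signature — for tests that need a large grid in
milliseconds; calibrated projections must be trained on real forward runs
via `table_from_replicates`.

## Meta-analysis across traits

Per-category enrichment folds are posterior means of per-iteration ratios
(category value over the genome-wide value computed from the same sampled
effects; iterations with a zero denominator are excluded and counted).
Across traits the median fold is reported, with
`s.e.m. = SD / sqrt(n_e)` and the effective number of independent traits
`n_e = (sum lambda)^2 / sum lambda^2` from the eigenvalues of the
phenotypic correlation matrix.

## Known limitations

- Chromosomes are modelled as independent; cross-chromosome correlation
  (e.g., from assortative mating) is not represented.
- `pi` counts SNPs with nonzero effects on the analysed panel, which is not
  an unbiased estimate of the number of causal variants when those are
  unobserved.
- The heterogeneous per-SNP residual variance driven by LD sampling error
  is a reconstruction (optional, off by default); the homogeneous default
  slightly understates uncertainty when the reference panel is small.
- The individual-level sampler is a small-scale reference implementation
  for equivalence testing, not a biobank-scale tool.
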