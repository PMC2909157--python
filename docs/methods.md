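# Methods

This note records the model, the algorithms and the conventions the package
uses, in its own notation. Animals are coded 1..q in a topologically sorted
pedigree (parents before offspring); code 0 is the unknown-parent sentinel.

## Breed composition and cross covariates

Each base animal declares its breed-A fraction `f_A` (purebreds 0 or 1);
non-base animals get the parent average `f_A(i) = (f_A(s) + f_A(d)) / 2`.
An animal with one known parent uses its own declared fraction for the
phantom parent. From the fractions come the mean-effect covariates used as
fixed regressions:

* direct breed composition: `f_A(i)`;
* direct heterosis: `f_A(s)(1 − f_A(d)) + (1 − f_A(s)) f_A(d)`, the
  probability that a random locus holds one allele of each breed origin;
* maternal breed composition and heterosis: the dam's direct values.

## Partial relationship matrices

For sources X ∈ {A, B, S} the tabular recursion is the classical one,

```
a_X(i, j) = ( a_X(s, j) + a_X(d, j) ) / 2        (j < i)
a_X(i, i) = base_X(i) + a_X(s, d) / 2
```

with source-specific diagonals of founder terms:

* breeds: `base_A(i) = f_A(i)`, `base_B(i) = 1 − f_A(i)`; this makes
  `A_A + A_B` equal the ordinary Wright NRM entrywise (a tested invariant);
* segregation: `base_S(i) = s_i = 2 [ f_A(s) f_B(s) + f_A(d) f_B(d) ]`,
  zero for purebreds and F1s, one for an F2.

All three matrices share the same gene-flow factor: `A_X = L D_X Lᵀ` with
the unit-lower-triangular `L` of the pedigree and diagonal per-source
Mendelian-sampling variances

```
d_X(i) = base_X(i) − [ a_X(s, s) + a_X(d, d) ] / 4 .
```

This shared factorisation justifies the row-wise (ancestor-tracing)
algorithm for the diagonals and the Henderson-style sparse inverse below.

### Contributors and collapsed matrices

An animal contributes to source X iff its diagonal `a_X(i,i)` is positive:
for breeds this is `f_X(i) > ε`, for segregation `s_i > ε` or having a
contributing parent (ε = 1e-12). Non-contributors have identically zero
rows and columns, so each `A_X` is stored and inverted *collapsed* to its
contributor set (the `M_X` index map). The collapsed inverse is assembled
by Henderson's rules restricted to contributors, with `1 / d_X(i)` weights;
paths through non-contributors carry zero and drop out exactly. A
contributing parent whose `d_X` falls below ε (e.g. a fully inbred animal)
raises `SingularContributorError` rather than producing an unusable
inverse.

## The linear model

Phenotype of animal i with dam m(i):

```
y_i = xᵢᵀ β + Σ_X [ a_oX(i) + a_mX(m(i)) ] + p(m(i)) + e_i
```

Fixed effects β: sex and age-of-dam factors, day-of-birth covariate, and
(optionally) the four breed-composition/heterosis regressions. Random
effects per source X: the stacked (direct | maternal) vector over
contributors has prior `N(0, G0_X ⊗ A*_X)` with 2×2 `G0_X`; dam permanent
environment `p ~ N(0, I σ²pe)`; residual `e ~ N(0, I σ²e)`.

The mixed-model equations are `C θ = Wᵀ y / σ²e` with

```
C = WᵀW / σ²e + blockdiag( I/k ,  { G0_X⁻¹ ⊗ A*_X⁻¹ }_X ,  I/σ²pe )
```

`k = 1e7` is a flat-prior ridge on the fixed effects that keeps `C` positive
definite without influencing the solutions materially. BLUP solves the
sparse system by LU with a residual check; total breeding values sum the
per-source solutions (zeros for non-contributors).

## Gibbs sampler

Single-site systematic scan over all location effects (a numba-compiled
kernel over the CSC columns of `C`), followed by the variance draws:

* `σ²pe`, `σ²e`: scaled inverse chi-squared full conditionals. With prior
  degrees of belief ν and scale s², sum of squares SS over n terms, the
  draw is `df·scale / χ²(df)` with `df = ν + n`,
  `scale = (ν s² + SS) / (ν + n)`.
* `G0_X`: inverse Wishart with `Ψ = ν_X G0⁰_X + S_X` and `df = ν_X + q_X`,
  where `S_X` stacks the quadratic forms `u'ᵀ (A*_X)⁻¹ u'` of the current
  direct/maternal solutions for source X. Note the convention: the prior
  *mean* of `IW(νG0⁰, ν + 3)`-style parameterisations differs from the
  scale; this package reports prior means as `Ψ / (df − p − 1)` with p = 2,
  and `PriorSpec.mean_covset()` applies exactly that.

Chains are reproducible: one `numpy` Generator seeded from the config; the
output file header carries the seed and a hash of priors + settings.
Outputs are one row per saved iteration with the eleven named components
`sigma2_Ao, cov_Ao_Am, sigma2_Am, sigma2_Bo, cov_Bo_Bm, sigma2_Bm,
sigma2_So, cov_So_Sm, sigma2_Sm, sigma2_pe, sigma2_e`.

## Posterior summaries and derived parameters

* Mode: Gaussian-kernel density estimate (Silverman bandwidth), argmax on a
  512-point grid.
* 95% HPD: shortest order-statistics window; never longer than the central
  interval (tested).
* ESS: initial-positive-sequence truncation of the FFT autocorrelation.

For a reference genotype group with weights `(w_A, w_B, w_S)` (F2 =
(0.5, 0.5, 1)):

```
V_o  = w_A σ²Ao + w_B σ²Bo + w_S σ²So          (and likewise V_m, C_om)
V_P  = V_o + V_m + C_om + σ²pe + σ²e
h²o  = V_o / V_P ,  h²m = V_m / V_P ,  r_om = C_om / sqrt(V_o V_m)
```

Derived parameters are computed per draw and summarised; the plug-in of
posterior means is also reported, since ratios of means and means of
ratios differ (Jensen gap — both appear in the test suite).

## Simulator

The built-in mating plan reproduces a 25-class crossbreeding design —
purebreds, reciprocal F1s, F2–F4 inter se, backcrosses in both orders,
three- and four-stage rotations and advanced crosses — scaled by a single
factor (`reference_plan(scale)`), with 60/40 base animals per breed and
family size 3 at full scale. Breeding values are drawn sequentially as
parent average plus `chol(G0_X) √d_X(i) z`; phenotypes add the fixed part
(package-chosen values: μ = 150, sex +8 for males, age-of-dam 0/5/8,
day-of-birth slope 0.3, breed and heterosis effects 5/3/10/5), the dam's
permanent-environment effect (shared within dam) and the residual.

The **gene-dropping oracle** is an independent check that never touches the
recursions: each base animal receives explicit allelic values at `n_loci`
unlinked loci (within-breed variance `σ²_X / (2 n_loci)` per locus, breed
means separated by `√(2 σ²_S / n_loci)`), inheritance is simulated allele
by allele, and the empirical covariance of total values across replicates
is compared with the assembled `G`, using the Monte Carlo standard error
`SE_ij = sqrt((C_ii C_jj + C_ij²) / R)`.

## Numerical choices and limitations

* ε = 1e-12 for contributor membership and singularity checks; ridge
  k ≥ 1e7 on fixed equations; sparse LU with a 1e-8 relative residual
  check for BLUP.
* Exactly two base breeds and a single trait; multi-breed (>2) extensions
  would add one partial NRM per breed pair for segregation.
* The sampler is single-site; mixing for the genetic covariances on small
  datasets is slow (see the ESS column of the worked example) — long
  chains with thinning are the intended production mode.
* Sex is not validated against sire/dam roles in hand-built pedigrees;
  the simulator assigns and respects sexes.
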