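# Methods

## Model

`dirdom` fits a SNP-level mixed model to repeated records (litters) of a
quantitative trait:

```
y = 1μ + h b + X t + W r + Q c + Z a + K d + e .
```

* `μ` — general mean (flat prior).
* `h b` — regression on the sow's average SNP homozygosity
  `h_i ∈ [0, 1]` (fraction of her non-missing SNPs that are homozygous);
  `b` (flat prior) is interpretable as inbreeding depression / heterosis
  in trait units per unit homozygosity. `h` is left uncentred; `μ`
  absorbs its mean.
* `X t` — fixed parity-order effects with 4 classes (1st, 2nd, 3rd, 4th
  and later). Flat priors on both `μ` and all parity levels leave the
  `μ + t` ridge improper, so the first class is constrained to zero (a
  corner parameterization); estimable contrasts are unaffected.
* `W r` — farm–year–month contemporary groups, `r ~ N(0, σ_r²)`.
* `Q c` — permanent environmental effect of each sow, `c ~ N(0, σ_c²)`.
* `Z a` — SNP additive effects, `a_j ~ N(0, σ_a²)`, frequency-centred
  coding `z_ij = x_ij − 2p_j` with `x_ij ∈ {0,1,2}`.
* `K d` — SNP dominance effects on the heterozygote-indicator coding
  `k_ij = 1{x_ij = 1} − 2p_j q_j`.
* `e ~ N(0, σ_e²)` residuals; the five variances carry scaled
  inverse-chi-square priors `ν S² / χ²_ν`.

Dominance effects take the additive-representation skew normal

```
d_j = λ u_j + ε_j ,   u_j = |N(0,1)| ,   ε_j ~ N(0, σ_d²) ,
```

so each `d_j | u_j ~ N(λ u_j, σ_d²)`. `λ` (flat prior) tilts the whole
distribution of dominance effects toward one sign while keeping its mode
near zero; `λ = 0` recovers the centred Gaussian prior. The mean and
variance of the marginal prior are `λ√(2/π)` and `σ_d² + λ²(1 − 2/π)` —
the reported `σ_d²` is always the *scale* parameter, not the full
variance, and the mapping above converts between the two. This
parameterization coincides with the common (Azzalini) skew normal under
`ω² = σ_d² + λ²`, `α = λ/σ_d`, which the test-suite uses as an
independent cross-check.

Four named models are reductions of the full one: SN (`b = 0, λ = 0`),
SC (`λ = 0`), AN (`b = 0`), Full (both free). SC expresses directional
dominance through the homozygosity covariate, AN through the skewed
prior; the two mechanisms describe the same aggregate trend, which is
why the Full model exhibits strong posterior correlation between `b` and
`λ` (the confounding checked in the acceptance suite).

## Gibbs sampler

Single-site Gibbs with incrementally maintained residuals, compiled with
numba. Per iteration, in fixed order: `μ`; `b` (if active); parity
levels 2–4; all group effects; all permanent-environment effects; all
`a_j` (ascending SNP index); all `d_j`; a recentering move (below); all
auxiliaries `u_j` and `λ` (if active); the five variances; a second
recentering move. All conditionals are standard Gaussian /
truncated-Gaussian / scaled-inverse-chi-square forms; the conditional
moment formulas live in one set of compiled functions shared by the
chain kernel and the Python-level `update_*` operations so tests
exercise exactly the arithmetic the kernel runs.

* location effect: mean `w'(e + w·old) / (w'w + σ_e²·prior_prec)`,
  variance `σ_e² / (w'w + σ_e²·prior_prec)`; `prior_prec = 0` for flat
  priors.
* `d_j`: variance `1/(k_j'k_j/σ_e² + 1/σ_d²)`, mean
  `v (k_j'y*/σ_e² + λu_j/σ_d²)`.
* `u_j`: `N(v λ d_j/σ_d², v)` with `v = 1/(1 + λ²/σ_d²)`, truncated to
  `[0, ∞)`.
* `λ`: `N(Σu_j d_j / Σu_j², σ_d²/Σu_j²)`.
* variances: `(sum_sq + νS²)/χ²_{n+ν}` with `sum_sq = Σ(d_j − λu_j)²`
  for `σ_d²` and plain sums of squares otherwise.

**Recentering move.** Because a record's homozygosity and heterozygote
fraction sum to one, adding `δ/m` to every dominance effect changes the
fit almost exactly like adding `δ` to `b` (plus a constant absorbed by
`μ`). Single-site updates therefore cross the `b`–mean(`d`) ridge
extremely slowly (ESS for `b` of ~5 per 1 500 draws in early versions).
The sampler adds an exact Gibbs update of the line coordinate `δ`
applied as `(b, d_j, μ) → (b + δ, d_j + δ/m, μ − δ(1 − mean 2pq))`: the
Gaussian conditional combines the prior terms `Σ(d_j + δ/m − λu_j)²` and
the exact (small) residual component along the direction
`v_i = h_i + (Σ_j k_ij)/m − (1 − mean 2pq)`, which is non-zero only
through missing-genotype imputation. This is a linear reparameterization
with unit Jacobian, so the draw leaves the posterior invariant; it
raises ESS(`b`) by roughly two orders of magnitude.

**Truncated-normal sampling.** For `N(m, v)` restricted to `[0, ∞)`:
plain accept–reject from the untruncated normal while the truncation
point is below 0.7 standardized units, Robert's (1995) shifted
exponential rejection beyond it. The Python-level operation uses scipy's
inverse-CDF truncated normal. Both stay finite and exact for
`m/σ ≪ 0` (stress-tested at −8σ).

**Initialization, seeding, checkpoints.** `μ` starts at the phenotype
mean, all other effects at 0, variances at their prior scales,
`u_j = √(2/π)`. Chains are independent with sub-seeds spawned from the
user seed (`numpy.random.SeedSequence`); a fixed seed gives bit-identical
draws. Every `check_every` (default 1 000) iterations the residual is
recomputed from scratch; the worst discrepancy is reported
(`max_resid_err`, asserted < 1e−8 in tests) and the fresh residual is
adopted. Non-finite state aborts with the iteration index.

**Hyperpriors.** Default `ν = 4.2` for all five variances; the scales
`S²` partition a phenotypic-variance guess (the sample variance of `y`)
as 10% additive, 5% dominance, 5% contemporary group, 10% permanent
environment, 70% residual, with the genetic shares divided by `Σ 2p_jq_j`
(additive) and `Σ (2p_jq_j)²` (dominance) to convert genetic variance to
per-SNP effect variance. These are weakly informative and proper; any
scale can be overridden.

## Derived quantities

Per retained draw: substitution effects `α_j = a_j + (q_j − p_j)d_j`;
`V_A = Σ 2p_jq_j α_j²`; `V_D = Σ (2p_jq_j d_j)²` (linkage-equilibrium
forms); heritability and dominance ratio against the full phenotypic
variance `V_P = V_A + V_D + σ_c² + σ_r² + σ_e²` (both environmental
random components belong to phenotypic variance). Summaries of ratios
are means of per-draw ratios, not ratios of means. Per-animal breeding
values `s_a = Z_c α` and dominance deviations `s_d = K_dev d` use the
classical orthogonal codes (`2 → −2q²`, `1 → 2pq`, `0 → −2p²`); both
have zero population mean under Hardy–Weinberg.

Expected inbreeding depression per 1% of inbreeding combines the two
mechanisms linearly:

```
I_D = 0.01 [ b · (1/m) Σ 2p_jq_j  −  Σ 2p_jq_j d_j ] .
```

Raising inbreeding by `F = 0.01` raises expected homozygosity by `F`
times the mean heterozygosity (covariate term) and multiplies every
SNP's heterozygote frequency by `1 − F` (dominance term). The formula is
the classical additive model of inbreeding depression with SNP dominance
effects standing in for causal ones; linearity in `F` is assumed, and
the two limiting cases (`b = 0`; `d = 0`) are unit-tested exactly.

## Genotype handling

Input dialects: a plain TSV (`id` + one column per SNP, `NA` missing)
and the PLINK `.raw` additive export. The counted allele is whatever the
file counts; MAF is `min(p, 1 − p)`. QC removes SNPs with MAF < 0.05 or
call rate < 0.95 first, then individuals with call rate < 0.95, then
recomputes frequencies once. Missing genotypes that survive QC are
mean-imputed (`x → 2p_j`, heterozygote indicator → `2p_jq_j`) for the
design matrices only; allele frequencies and the homozygosity covariate
use observed calls exclusively, so imputation cannot bias `h` or `p`.

## Model comparison

Per-observation Gaussian log-likelihoods conditional on all location
effects and `σ_e²` (the conditional deviance focus — the compared models
differ in their SNP-effect priors, and the fitted values already
marginalize nothing). `DIC = D̄ + pD` with
`pD = D̄ − D(posterior means)`, the plug-in using posterior-mean fitted
values (valid by linearity) and posterior-mean `σ_e²`; negative `pD`
triggers a warning but is returned. `CPO_i` is the harmonic mean of the
record's likelihood over draws, computed with log-sum-exp; `LogCPO` is
the summed log. The harmonic-mean estimator is noisy by nature; both
criteria are checked for stability under draw-thinning in the tests.

## Synthetic data

The generator emulates the structure of commercial pig litter-size
datasets, which are proprietary:

| parameter | default | rationale |
|---|---|---|
| sows / SNPs | 500 / 2 000 | desk scale; real datasets are ~3 000 sows, ~37 000 SNPs |
| records per sow | 1–5, mean 3 (probs 0.10/0.25/0.30/0.25/0.10) | repeated litters, parity = record number capped at 4 |
| contemporary groups | records/4 | matches the ~4 records/group of real farm–year–month grouping |
| allele frequencies | uniform on [0.05, 0.95] | post-QC spectrum |
| missing rate | 0.01 | typical chip missingness |
| per-sow inbreeding `F_i` | N(0.05, 0.07²) truncated to [0, 0.35] | genotypes drawn with P(het) = 2pq(1 − F_i); commercial lines vary in genomic inbreeding, and var(h) beyond binomial noise is what makes `b` estimable at desk scale |
| `μ` | 11.7 piglets | litter-size mean |
| `b_true` | −12 | piglets per unit homozygosity |
| `λ_true` | 0.0075 | chosen so `m·λ√(2/π) ≈ 12`, the same aggregate directional trend as `b_true` expressed through 2 000 skewed dominance effects |
| `σ_a²`, `σ_d²` (per SNP) | 1.0e−3 / 1.7e−3 | realized `V_A ≈ 0.9`, `V_D ≈ 0.5` trait units² |
| `σ_r²`, `σ_c²`, `σ_e²` | 0.16 / 0.50 / 6.57 | phenotypic SD ≈ 2.9 |

The phenotype is built through the same design encodings the sampler
uses (verified by an equality test), with `b_true` acting on realized
per-sow homozygosity, parameterized against its sample mean so the
phenotype mean stays at `μ`. The truth file records the drawn effects
and the realized `V_A`, `V_D`, `I_D` via the same code path as the
estimator.

**What the generator does not emulate:** linkage disequilibrium,
pedigree relatedness, selection, genotyping error, and non-Gaussian
litter-size residuals. Passing recovery tests therefore show that the
estimator inverts its own generative model at realistic
signal-to-noise — not that real pig data meet these assumptions.

## Scaled-down study sizes

Desk-scale fits in the tests and the acceptance script use 1 chain of
2 000–3 000 iterations (500–1 000 burn-in) on 500 sows / ~1 500 records
/ 2 000 SNPs; the model-ranking study uses 200 sows / 500 SNPs; the
closed-form-oracle check uses 8 records / 3 SNPs with 50 000 draws.
Library defaults for real analyses are 5 chains of 7 500 iterations with
2 500 burn-in, and longer for the Full model, whose `b`–`λ` confounding
mixes worst.

Two desk-scale behaviours are worth knowing. First, `b` is partially
attenuated toward zero relative to its generating value: the prior on
the absorbable dominance trend has standard deviation `√(m σ_d²)`, which
at `m = 2 000` is not negligible against the likelihood's information on
`b`, so part of the signal is booked to the dominance mean. At full data
scale the same mechanism is much weaker. Second, `σ_a²`/`σ_d²` (hence
`V_A`, `V_D`, `h²`, `d²`) mix slowly in short single chains — their ESS
in the README demonstration is ~5 — so variance-component inference
should use the multi-chain defaults.

## Numerical and design choices

* HPD interval: shortest window over sorted draws; ties break to the
  first (lowest) window.
* ESS: `n / (1 + 2Σρ)` with Geyer's initial-positive-sequence
  truncation, capped at `n`; a constant chain returns 0 with a warning.
* Geweke drift z: first 10% vs last 50% window means, each variance
  estimated by the same truncated-autocovariance spectral estimator.
* Gelman–Rubin and Raftery–Lewis diagnostics are not implemented; ESS,
  the Geweke statistic and the per-chain trace export cover convergence
  checking, and any external MCMC toolkit can consume the TSV traces.
* A `fixed_variances` mode exists solely so tests can compare the
  sampler with closed-form Gaussian posteriors; `lambda_clamped` keeps
  the auxiliary machinery running with `λ` pinned at 0 so the nesting of
  the symmetric models inside the asymmetric ones can be verified.
* The centred (`freq`) design coding is the default; `centering="none"`
  is retained for testing — `b` and `λ` are invariant, `μ` shifts.

## Known limitations

Single-site updates make each sweep O(records × SNPs); genome-scale data
(tens of thousands of SNPs, >10⁴ records) are feasible but slow in this
implementation, and an equivalent formulation through genomic
relationship matrices would be preferable there. The skew prior is
univariate per SNP — no multivariate asymmetry linking additive and
dominance magnitudes, no genome-local directional dominance, no
epistasis. `I_D` assumes linearity in `F`. The harmonic-mean CPO
estimator can be unstable for records far in the tails.
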