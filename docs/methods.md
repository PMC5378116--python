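# Methods

## The model

`iimcoal` fits *isolation-with-initial-migration* (IIM) models to pairwise
nucleotide differences at many independent loci. Forward in time, an
ancestral Wright–Fisher population of relative size `a` splits `tau0`
(units of `2N` generations, `N` = size of subpopulation 1 during gene
flow) ago into two subpopulations of relative sizes `1` and `b` that
exchange migrants at scaled rates `M1 = 4N m1` and `M2 = 4N m2`
(backward-in-time immigrant fractions); at `tau1 <= tau0` gene flow stops
and the populations continue in isolation at relative sizes `c1` and `c2`.
Setting `tau1 = tau0` removes the isolation stage, `tau1 = 0` removes the
migration stage, and `M1 = M2 = 0` gives pure isolation; these limits are
handled exactly, not by epsilon offsets.

A locus contributes one pair of haploid sequences in one of three sampling
states (1: both from population 1, 2: both from population 2, 3: one from
each). Under the infinite-sites assumption, the number of segregating
sites satisfies `S | T ~ Poisson(theta_j T)`, where `T` is the pairwise
coalescence time and `theta_j = r_j * theta` the locus mutation rate
(relative rates `r_j` treated as known).

## Coalescence-time distributions

Backward in time the genealogy is a succession of three Markov chains (one
per stage). The isolation and ancestral stages are Kingman coalescents
(exponential absorption at rates `1/c_i` and `1/a`). For the migration
stage, the absorption time of the structured chain with generator on
states (1, 3, 2, coalesced) is a mixture of three exponentials,

    f_mig(i)(t) = sum_j A[i, j] * lam_j * exp(-lam_j t).

With gene flow in both directions, `lam` and `A` come from a dense
eigen-decomposition of the 4x4 generator (`lam` = absolute values of the
three negative eigenvalues, `A[i, j] = -R[i, j] * Rinv[j, 4]` with `R` the
right eigenvectors). For unidirectional gene flow the eigen-system is
replaced by fully explicit coefficients derived by conditioning on the
first transition and partial-fraction decomposition of the
moment-generating functions; with no gene flow the mixture degenerates to
the obvious exponentials (with a defect row for state 3, which cannot
coalesce before `tau0`). All four regimes are verified in the test suite
against a matrix-exponential oracle to 1e-9.

Numerical choices:

* Decay rates are sorted descending with a deterministic eigenvector
  tie-break, so the `Spectrum` is reproducible. Note that under this
  ordering the component that vanishes in the symmetric case
  (`M1 = M2`, `b = 1`) is the one with rate `1 + M`, which is not always
  the third; tests identify it by its rate.
* Nearly coincident decay rates (a measure-zero parameter set on which the
  closed-form coefficients blow up, e.g. `M2 = 2`) are lifted by
  multiplicative perturbation of `(M1, M2, b)` of order 1e-9 and the
  spectrum recomputed; the likelihood is continuous there, so the error is
  far below statistical noise.
* Imaginary parts below 1e-9 (relative) are truncated; anything larger
  raises instead of being silently discarded.

## The segregating-sites PMF

Because the density of `T` is a piecewise mixture of (shifted)
exponentials, `P[S = s]` is a finite sum of geometric-type terms, one per
stage. Every truncated Poisson sum is expressed as a regularized
incomplete-gamma value (`PoisCDF(s; x) = Q(s+1, x)`), never accumulated
term by term at full scale, and the re-basing factor `exp(lam * tau1)` is
carried in log space; geometric factors `(c theta)^s / (1 + c theta)^(s+1)`
are evaluated from logs. This keeps the log-PMF finite and accurate for
counts in the tens of thousands (checked against 50-digit decimal
arithmetic).

For the bulk of realistic inputs (s <= 600, all exponent arguments under
600) a compiled fast path evaluates the same formulas in linear space from
Poisson-pmf recurrences, with all transcendental functions batched as
vector operations; inputs outside the guarded region fall back to the
log-space path element-wise. The two paths agree to ~1e-13 in log
probability, and the fast path makes a 40,000-locus log-likelihood
evaluation take a few milliseconds, which is what keeps a full model fit
in the tens of seconds.

Negative intermediate values within -1e-12 (relative, from cancellation
between signed mixture terms) are clamped to zero; anything more negative
raises.

## Likelihood and fitting

The multilocus log-likelihood is the sum of per-locus log-PMFs; the
mixture spectrum is computed once per parameter vector, so per-locus work
is O(1). Fitting uses the mutation-scaled parameterization
`phi = (theta_a, theta, theta_b, theta_c1, theta_c2, T1, V, M1, M2)` with
`T1 = theta tau1`, `V = theta (tau0 - tau1)`, which decouples the mutation
rate from the coalescent time scale. Model variants are masks over phi:

| model | free parameters | fixed / tied |
|-------|-----------------|--------------|
| ISO   | theta_a, theta, theta_b, V | T1 = M1 = M2 = 0; c-sizes tied to migration-stage sizes |
| IM1   | + M1, M2        | T1 = 0; ties as ISO |
| IIM1  | + T1            | ties as ISO |
| IIM2  | all nine        | — |
| IIM3  | IIM2 without M1 | M1 = 0 |

Optimization is over log-transformed positive parameters (bounds ±25 nats)
and untransformed migration rates bounded below by zero. Each start is a
Nelder–Mead simplex search followed by a bounded L-BFGS-B polish
(relative log-likelihood tolerance 1e-8); starts are a moment-style
initialization (per-state means of `s/r` matched to the leading behaviour
of `theta E[T(i)]`), Latin-hypercube jitter around it, and — for models
with gene flow — warm starts promoted from a cheap ISO fit, which reliably
lands the search in the right basin. The best start gets a final refine
pass. Fits are deterministic given `(data, model, n_starts, seed)`.

Hessians use central finite differences with step `1e-4 * (1 + |phi_k|)`;
when an estimate sits within a step of a bound the stencil centre shifts
just inside the domain. Wald intervals invert the negative Hessian (with a
logged warning near boundaries); profile intervals bisect the profile
log-likelihood drop of `0.5 * chi2_1(level)` (1.9207 at 95%),
re-optimizing the remaining parameters at each probe with warm starts.

Conversions to demographic units use `N_x = theta_x / (4 mu)`,
`t = (g / 2 mu) * (mutation-scaled age)`, `q1 = mu M2 b / theta`,
`s1 = M2 b / 2`, with `mu` calibrated from outgroup divergence by the
molecular clock (`mu = kbar * g / (2 t_div)`). Uncertainty on the
converted scale recomputes the Hessian in the conversion parameterization
`(theta_a, theta, theta_b, theta_c1, theta_c2, T1, T1+V, M2 b / theta)`
(and the `M2 b` variant for `s1`) rather than chain-ruling, and applies
the diagonal linear map; profile intervals map through the same monotone
scaling.

## Model selection and clustered loci

Likelihood-ratio tests use `D = 2 (logL1 - logL0)` against a chi-square
with df equal to the free-parameter difference (ISO→IM1: 2, IM1→IIM1: 1,
IIM1→IIM2: 2, IIM2→IIM3: 1). When the null fixes parameters on the
boundary of the alternative (migration rates or the isolation time at
zero) the correct null is a chi-square mixture with fewer df, so the naive
p-value is conservative; `boundary_null_study` verifies this empirically
by a simulate/fit/fit pipeline, and every such test carries a boundary
flag. Forward selection steps through the nested ladder while the null is
rejected, then prunes boundary-valued parameters whose removal leaves the
likelihood unchanged.

When loci are linked the product likelihood is a composite likelihood:
estimates remain consistent but Fisher standard errors are too small.
`godambe` estimates the score covariance from block-wise score sums
(`V = sum_j U_j U_j'`, central-difference scores with the same step policy
as the Hessian) and returns the sandwich `G^-1 = H^-1 V H^-1`. The robust
LRT uses the weighted-chi-square null `D ~ sum_i w_i chi2_1` with weights
the eigenvalues of `(H^pp)^-1 G^pp` (tested-parameter blocks of the
inverse matrices, nuisance parameters profiled), moment-matched to a
scaled-shifted chi-square `c chi2_df + d`. With singleton blocks and a
correctly specified model the weights are ~1 and the robust p-value
reduces to the naive one; whether the approximation stays conservative
for boundary nulls is unknown, and the boundary flag is attached to
robust results too. A `block_reduce` utility labels consecutive runs of
loci (genome order) as blocks and can discard every other run so retained
blocks are effectively independent; a trailing partial run counts as a
block.

## The simulator

`simulate_dataset` reproduces the canonical study conditions: per data
set, exactly 1/4 of loci in state 1, 1/4 in state 2, 1/2 in state 3;
relative rates drawn from Gamma(15, 15) (mean 1, sd 0.258) or supplied as
a fixed vector; coalescence times drawn exactly from the piecewise law by
a vectorized stochastic simulation of the two-deme chain (competing
exponentials within each epoch, memoryless censoring at epoch
boundaries); counts Poisson with mean `r_j theta T`. A single integer
seed drives a counter-based (Philox) generator, so data sets are exactly
reproducible. `simulate_multiepoch` generalizes to any piecewise-constant
two-deme history (the IIM model is its three-epoch special case, verified
distributionally), and ships two clearly labelled *illustrative*
misspecification scenarios (gradual divergence, secondary contact) — these
are representative configurations, not reproductions of any published
figure.

What the generator emulates — and does not: data are ideal draws from the
model itself (free recombination between loci, none within, infinite
sites, known relative rates, constant sizes within stages). Passing
recovery tests therefore demonstrates correctness and calibration of the
estimator under the model's own assumptions, not robustness to real-data
violations such as intralocus recombination, linkage, rate-estimate error
or finite-sites mutation.

## Study conditions and problem sizes

The simulation studies use the canonical generating values
`a = 0.75, theta = 2, b = 1.25, c1 = 1.5, c2 = 2, tau0 = 2, tau1 = 1,
M1 = 0.5, M2 = 0.75` (i.e. `theta_a = 1.5, theta_b = 2.5, theta_c1 = 3,
theta_c2 = 4, T1 = V = 2`) and data sets of 8,000 or 40,000 loci. The
boundary-conservativeness study in this package runs 20 replicate data
sets of 8,000 loci (generating values: the ISO maximum-likelihood
estimates from the Drosophila analysis); the recovery study runs 13
replicates of 40,000 loci in `scripts/acceptance.py` and 5 in the test
suite. Replicate counts are the package's choice of a desk-scale design:
medians stabilize with more replicates, and the seeds make every run
reproducible.

## Known limitations

* **A soft ridge couples the gene-flow-period parameters.** At the study's
  generating values the observed information at 40,000 loci leaves
  `theta, theta_b, T1, V, M1, M2` strongly correlated: single-replicate
  maximum-likelihood estimates of `theta` commonly deviate by 25% or more
  with log-likelihood gains of only a few units over the generating
  values, and migration-rate estimates are right-skewed with a point mass
  near zero. This is a property of the model and design (it matches the
  published observations of skewness and occasional far outliers), not of
  the optimizer: fits started from the generating values converge to the
  same distant optima. Replicate medians are well behaved for `theta`;
  migration-rate medians converge more slowly.
* Estimation near `V = 0`, very large `T1`, or `M > 1` is unstable (the
  data carry almost no information about the gene-flow period there).
* Two sequences per locus only; two demes; no intralocus recombination or
  finite-sites correction; relative rates are treated as known constants,
  so their estimation error is not propagated.
* The real-data reproduction requires the original supplementary loci
  table, which is not redistributable inside this repository; see
  `scripts/convert_file_s4.py`.
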