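# iimcoal

Maximum-likelihood inference for **isolation-with-initial-migration (IIM)
models** of speciation from pairwise segregating-site counts at many
independent loci.

In the IIM model an ancestral population (relative size *a*) splits τ₀
coalescent time units ago into two populations (sizes 1 and *b*) that
exchange migrants at scaled rates *M₁* = 4*N*m₁ and *M₂* = 4*N*m₂ until
time τ₁, after which they evolve in complete isolation (sizes *c₁*, *c₂*).
It interpolates between the classic isolation and isolation-with-migration
models and lets you ask, with likelihood-ratio tests, whether two
diverging species (a) never exchanged genes, (b) exchange genes to this
day, or (c) exchanged genes for an initial period only — and, in case (c),
when gene flow stopped.

The data are minimal and genome-scale friendly: for each locus, one pair
of haploid sequences summarized as a sampling state (1: both from
population 1; 2: both from population 2; 3: one from each), the count *s*
of nucleotide differences, and a relative mutation rate *r* (from outgroup
divergence). Under the infinite-sites model, *S* | *T* ~ Poisson(θ*T*)
with θ = 4*N*μ, and the coalescence-time density of *T* is a piecewise
mixture of exponentials obtained from the eigen-decomposition of the
structured-coalescent generator (closed forms under unidirectional or
absent gene flow). The PMF of *S* is therefore fully analytic, and fitting
tens of thousands of loci takes seconds to minutes, not hours.

The package provides:

- exact densities, CDFs and means of pairwise coalescence times in all
  four migration regimes (`coalescent_core`);
- a numerically stable PMF of the number of segregating sites, accurate
  up to tens of thousands of mutations (`segsites`);
- multilocus maximum-likelihood fitting of the nested model family
  ISO ⊂ IM1 ⊂ IIM1 ⊂ IIM2 (⊃ IIM3), Wald and profile confidence
  intervals, and conversion to individuals/years with delta-method
  intervals (`inference`);
- likelihood-ratio model selection with boundary-aware (conservative)
  p-values, and Godambe (sandwich) standard errors plus robust LRTs for
  linked loci clustered in blocks (`model_selection`);
- an exact coalescent simulator for the IIM model and for arbitrary
  piecewise-constant two-deme histories (`simulator`);
- TSV input/output, outgroup-based relative-rate estimation, block
  reduction and an `iimcoal` command-line interface (`io_cli`).

## Worked example

Simulate 8,000 loci under a one-directional IIM model and fit it back:

```python
import iimcoal as ic

phi = ic.MODELS["IIM3"].build_phi(dict(
    theta_a=1.5, theta=2.0, theta_b=2.5, theta_c1=3.0, theta_c2=4.0,
    T1=2.0, V=2.0, M2=0.75))
data = ic.simulate_dataset(ic.SimConfig(phi=phi, n_loci=8000, seed=42))
fit = ic.fit(data, "IIM3", n_starts=3, seed=1)
```

Printing the fit, a Wald interval and the converted times
(`ic.wald_ci(fit)`, `ic.convert(fit, g=0.1, mu_hat=2.31e-7)`) gives:

```
logL = -17879.40
  theta_a   =  1.348
  theta     =  2.038
  theta_b   =  1.474
  theta_c1  =  2.986
  theta_c2  =  3.739
  T1        =  2.159
  V         =  2.499
  M2        =  1.999
theta_c1 95% Wald CI: (2.667, 3.305)
t0 = 1.008 My, t1 = 0.467 My, s1 = 0.723
```

Reading the output: the parameters are mutation-scaled — θ_x = θ·x for the
relative sizes, T₁ = θτ₁ and V = θ(τ₀ − τ₁), so the divergence span is
T₁+V ≈ 4.7 expected mutations per locus pair. The well-identified
size parameters (θ_c1 here: truth 3.0, estimate 2.99 with CI
(2.67, 3.31)) and θ itself (truth 2.0, estimate 2.04) come back close to
the generating values at this sample size, while the gene-flow-period
parameters (M₂: truth 0.75, estimate 2.0) sit on a well-documented soft
likelihood ridge and are individually noisy until the number of loci gets
very large — see `docs/methods.md`. The converted times use a generation
time of 0.1 years and a per-locus mutation rate of 2.31×10⁻⁷: the split
is placed ~1.0 Mya and the end of gene flow ~0.5 Mya for these simulated
data.

The same analysis from the shell:

```sh
iimcoal simulate --preset batch1 --seed 42 --out loci.tsv
iimcoal fit --model IIM3 --data loci.tsv --starts 3 --seed 1 --out fit.json
iimcoal select --sequence ISO,IM1,IIM1,IIM2 --data loci.tsv --alpha 0.05
```

To analyse real data, prepare a tab-separated table with columns
`locus_id  state  s  rel_rate` (see `iimcoal.read_loci`;
`scripts/convert_file_s4.py` converts the supplementary Drosophila table
of the original study into this format and records its checksum).

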