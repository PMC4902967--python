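# Methods

## Model and assumptions

`fisdyn` models one locus in a closed population of constant size *N*
diploid, monoecious individuals (ramets) with non-overlapping
generations. Each generation applies, in order, mutation, reproduction
and drift (the cycle in `fisdyn.kernel`). The assumptions inherited from
this structure:

* **Symmetric k-alleles mutation.** Every allele copy mutates
  independently with total rate μ, landing uniformly on the *n* − 1
  other alleles. There is no mutational bias, no stepwise structure and
  no gene conversion (conversion-like processes, which depend on the
  partner allele within an individual, would drive homozygote excess
  instead and are outside the model).
* **Partial clonality without fecundity differences.** A fraction *c*
  of offspring are exact copies of a uniformly chosen parent; the rest
  come from random union of gametes, which includes selfing at rate
  1/*N*. There is no selection, no assortative mating, no separate
  sexes.
* **Genotype-level drift.** The next generation is a multinomial sample
  of *N* individuals from the post-reproduction genotype frequencies.
  Drift therefore acts on genotypes, not alleles — under partial
  clonality Hardy–Weinberg proportions cannot be assumed, so allele
  frequencies do not carry enough information.
* **Unlinked loci.** Multilocus quantities treat loci as i.i.d.
  realisations of the single-locus chain; linkage and clonal
  identity-across-loci are not modelled.

F_IS = (H_e − H_o)/H_e per state, undefined when H_e = 0 (one allele
left). The undefined case is carried as an explicit sentinel
(`None`/missing), never as silently propagating NaN arithmetic, and
fixed states are excluded (with renormalisation) from all conditional
summaries.

## Parameters

| parameter | meaning | range | default/notes |
| --- | --- | --- | --- |
| `N` | population size (ramets) | ≥ 1 | no default; exact analysis practical to a few hundred for n = 2 |
| `n` | alleles at the locus | ≥ 2 | 2; state count grows as N^(g−1)/(g−1)! |
| `c` | clonal fraction of offspring per generation | [0, 1] | 0 |
| `mu` | per-generation, per-allele-copy mutation rate | [0, (n−1)/n] | 0 |
| `epsilon` | acceptable error for convergence criteria | (0, 1) | 1/(2N): half the smallest genotype-frequency step resolvable by exhaustively sampling N individuals |
| state cap | refusal threshold for exact enumeration | — | 2×10⁶ states; beyond it the Monte Carlo path applies |
| near-fixation threshold | top allele frequency above 1 − √(1/(2N)) | — | loci above it are dropped from multilocus sampling, mimicking how near-monomorphic markers are discarded in practice |

## Exact chain analysis

The transition matrix is column-stochastic (column = current state);
multinomial probabilities are assembled in log space via log-gamma, so
N! never overflows, and frequencies in (−10⁻¹⁵, 0) from rounding are
clamped to zero first. Matrices are dense; for N = 100, n = 2 (5151
states) the matrix takes ~210 MB and builds in seconds.

* **Steady state** (μ > 0 makes the chain irreducible): power iteration
  until successive iterates differ by < 10⁻¹² in total variation, with a
  direct null-space solve (`method="linear"`) as cross-check; both agree
  to ~10⁻¹² on the 5151-state chain. With μ = 0 the chain is reducible
  and `steady_state` refuses; the drift-only case (c = 1, μ = 0) routes
  to the absorption analysis.
* **Mixing time**: smallest *t* with worst-case (over pure starts)
  total-variation distance to the steady state below ε. Total variation
  is the standard chain metric and ε = 1/(2N) is reused as threshold.
  All starts are tracked at once (iterating *M* on the identity), which
  restricts this diagnostic to chains small enough to enumerate. Note
  that this full-distribution time is limited by the mutation mode and
  is essentially independent of *c*; the quantity clonality visibly
  slows is the convergence of the *mean* F_IS trajectory.
* **Drift absorption** (c = 1, μ = 0): the absorbing set is the *g*
  monomorphic-genotype states (all N individuals sharing one genotype —
  final F_IS 0 via homozygote fixation or −1 via a surviving
  heterozygous clone). Expected first-passage times solve
  (I − Q)t = 1 on the transient block; t_N is the maximum over starts,
  attained near the maximally mixed states. t_N is an exact expectation
  here, not an ε-criterion, because absorption is a genuine stopping
  event.

## Timescales and the dominance map

t_c and t_μ are the closed-form geometric-progression times (each
force's residual deviation shrinks by factor *c*, respectively
1 − μn/(n−1), per generation). Integer reporting uses the ceiling of the
real value; ±1 generation should be treated as equivalent, as rounding
conventions for such times vary. The drift law t_N = σN − τ is fitted by
least squares through exact absorption times; the default grid is
N ∈ {10, 20, …, 60} (largest solve: 1891 states), which keeps the cached
fit interactive. The fitted law is linear to better than 2 % on the grid
and extrapolates to N = 100 within a few percent of the directly solved
value (σ ≈ 1.61, τ ≈ 1.3 for n = 2; the slope grows with n). Boundary curves
of the dominance map come from exact pairwise equality of the
implemented formulas: t_c = t_μ at c = 1 − μn/(n−1), t_c = t_N at
c = ε^(1/(t_N − 1)), t_μ = t_N at μ = (n−1)/n · (1 − ε^(1/(t_N − 1))).

## Equilibrium reference model

The closed form mean F_IS,∞ = 1/((2N − 1) − 2N/(cγ)), γ = (1 − μ)², is
the single-population specialisation (q_s = 1, q_d = 0, selfing 1/N) of
a classical infinite-alleles metapopulation result; the general form is
kept internally and reduces to it. The companion recursion on the
identities (F, Θ) = (1 − H_o, 1 − H_e) is affine,
(F, Θ)ₜ₊₁ = γ(A(F, Θ)ₜ + b) with A = [[c + (1−c)/(2N), (1−c)(1−1/N)],
[1/(2N), 1 − 1/N]] and b = [(1−c)/(2N), 1/(2N)]; its fixed point (from
the 2×2 linear solve) equals the closed form to ~10⁻¹² across the
tested (c, μ, N) grid. The constant (1−c)/(2N) in the first slot is the
selfing contribution — a sexual offspring selfs with probability 1/N
and then carries identity (1 + F)/2; this is the only constant for
which the recursion and the closed form are consistent.

Because this model assumes infinitely many alleles and continuous
heterozygosities, it diverges from the finite-allele chain where
mutation is strong: at c = 1, μ = 10⁻², N = 100 the closed form gives
≈ −0.20 while the two-allele chain's steady mean (recomputed by the
acceptance script) is ≈ −0.11, shrinking further toward 0 as mutation
strengthens. Back-mutation among few alleles keeps
heterozygosity higher than the infinite-alleles accounting admits, so
the reference model should be read as an upper bound on |mean F_IS| in
that regime.

The inversion c = 2N/(γ((2N − 1) − 1/F̄)) is exact for F̄ < 0; it is
insensitive to μ across [10⁻¹², 10⁻³] (variation < 0.005 in c for the
N = 247 example) and clips marginally super-unit results (possible near
F̄ = −1 with μ > 0) to 1 with a warning.

## Monte Carlo simulator and what it does (not) emulate

The simulator advances many unlinked loci in lock-step: the
deterministic maps are applied vectorised across loci and the next
counts drawn from per-locus multinomials out of a single seeded PCG64
stream. Runs are bit-reproducible for fixed (seed, n_loci, t_max); the
generation-major draw order means changing n_loci changes the stream,
so replicate counts are part of the experiment's identity. The
simulator emulates exactly the chain's law (verified by chi-square
agreement of state occupancies against exact propagation on small
systems), hence it shares all the model's idealisations: no genotyping
error, no missing data, no spatial or clone-structure sampling bias, no
linkage. Passing sampling tests therefore says nothing about those
real-data complications — only about pure finite-panel noise, which is
already enough to exceed ±0.1 deviations with 10 loci in transient
highly clonal populations.

Multilocus panels draw loci i.i.d. (conditioned on not near-fixed) from
either an exact state distribution or a simulation snapshot. The "true
mean" in deviation reports is the exact conditional mean when the
source is exact, and the full-replicate-pool conditional mean for
simulation sources.

## Numerical choices

* Genotype order: lexicographic allele pairs (i ≤ j); state order:
  colexicographic over counts. Both are arbitrary but frozen — indices
  are stable across runs and releases.
* Isoplethic presets with indivisible N round by largest remainder,
  preferring heterozygote classes, and warn; this biases the rounding
  against spurious homozygote excess.
* Weighted quantiles use the left-continuous inverse CDF on the sorted
  support; histograms aggregate exactly equal F_IS values.
* `fis_summary` excludes fixed states by default; the near-fixed
  exclusion is the default only on the multilocus sampling path, where
  it mirrors marker-selection practice. Both paths accept the other
  flag.
* Power iteration declares convergence on successive-iterate total
  variation < 10⁻¹² (configurable); absorption and steady-state linear
  solves use LAPACK directly.

## Limitations

* Exact analysis is dense-matrix: memory grows as the square of the
  state count, which itself grows fast with n; n = 2 up to N ≈ a few
  hundred is the practical exact range, everything else is Monte Carlo.
* σ(n), τ(n) have no analytic form; fits beyond the grid are
  extrapolations and flagged as such by the recorded fit range.
* The de Finetti export is biallelic by construction.
* Overlapping generations, migration, selection, unequal per-allele
  mutation rates and time-varying c are not modelled.
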