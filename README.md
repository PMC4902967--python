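# fisdyn

Temporal dynamics of genotype frequencies and the inbreeding coefficient
F<sub>IS</sub> in finite, partially clonal diploid populations.

Many plants, fungi, corals and protists mix clonal reproduction (a
fraction *c* of offspring copy their parent's genotype) with sexual
random mating (the remaining 1 − *c*, including selfing at rate 1/*N*).
Field studies routinely read negative multilocus F<sub>IS</sub> as a
signature of nearly exclusive clonality, using equilibrium formulas.
`fisdyn` is for population geneticists who want to go beyond that
equilibrium reading: it computes the *transient* behaviour — how long a
population of size *N* with mutation rate *μ* actually takes to reach
its steady state, what the full distribution of F<sub>IS</sub> looks
like on the way, and how badly a finite panel of loci can misestimate
the mean.

## The model

One locus with *n* alleles has *g* = *n*(*n* + 1)/2 genotypes; the
population state is the vector of counts *q* of *N* individuals over
those genotypes (there are C(*N* + *g* − 1, *g* − 1) such states). Each
generation the genotype frequencies *ν* = *q*/*N* are transformed
deterministically and then resampled:

1. **Mutation** (symmetric *k*-alleles): each allele copy keeps its
   identity with probability α = 1 − μ or becomes one of the *n* − 1
   others with probability β = μ/(*n* − 1) each, giving *ν*<sub>I</sub>.
2. **Reproduction**: *ν*<sub>III</sub> = *c* *ν*<sub>I</sub> +
   (1 − *c*) · HWE(*p*<sub>I</sub>), where *p*<sub>I</sub> are the
   gamete-pool allele frequencies and HWE(*p*) the Hardy–Weinberg
   proportions *p*<sub>i</sub>², 2*p*<sub>i</sub>*p*<sub>j</sub>.
3. **Drift**: the next state is multinomial,
   *X*<sub>t+1</sub> ~ ℳ(*N*, *ν*<sub>III</sub>).

Stacking the multinomial laws for all states gives a column-stochastic
transition matrix *M*; distributions over states propagate as
*x*<sub>t</sub> = *M*<sup>t</sup> *x*<sub>0</sub>, and every per-state
quantity — allele frequencies, H<sub>o</sub>, H<sub>e</sub>,
F<sub>IS</sub> = (H<sub>e</sub> − H<sub>o</sub>)/H<sub>e</sub> —
becomes a distribution with the state distribution as its law.

On top of the chain the package provides:

* **Per-process convergence times** with acceptable error ε = 1/(2*N*):
  t<sub>c</sub> = 1 + log ε / log *c* (reproduction),
  t<sub>μ</sub> = 1 + log ε / log(1 − μ*n*/(*n* − 1)) (mutation), and the
  drift law t<sub>N</sub> ≈ σ*N* − τ with σ, τ fitted from exact
  first-passage times to genotypic uniformity. The smallest of the three
  identifies the dominant evolutionary force at a parameter point.
* **An equilibrium reference model** (infinite-alleles, continuous
  heterozygosities): mean F<sub>IS,∞</sub> = 1/((2*N* − 1) −
  2*N*/(*c*(1 − μ)²)), its algebraic inversion for *c* from an observed
  multilocus mean, and the underlying two-variable identity recursion.
* **A seeded Monte Carlo simulator** of unlinked loci for parameter
  ranges beyond exact tractability, plus the multilocus sampling
  analysis: means over panels of *L* loci and their mean signed
  deviation from the exact mean, with loci near fixation (top allele
  frequency above 1 − √(1/(2*N*))) excluded as in empirical practice.

## Worked example

A highly clonal population (*c* = 0.99, μ = 10⁻⁶, *N* = 100):

```bash
$ fisdyn timescales --N 100 --c 0.99 --mu 1e-6 --sigma 1.6074 --tau 1.3181
{
  "N": 100,
  "n": 2,
  "c": 0.99,
  "mu": 1e-06,
  "epsilon": 0.005,
  "t_c": 528.1781404899169,
  "t_mu": 2649157.0341853313,
  "t_N": 159.4219,
  "dominant": "drift"
}
```

Reproduction alone would need ~529 generations to erase a deviation from
Hardy–Weinberg, mutation ~2.6 million; genetic drift (t<sub>N</sub> ≈ 159
generations to genotypic uniformity) is the fastest force, so this
population's genotype dynamics are drift-dominated: loci drift towards
fixation or towards a single surviving heterozygous clone, and the
population keeps a long "evolutionary memory" of its past composition.

The equilibrium reference model for the same parameters predicts a
strongly negative mean:

```bash
$ fisdyn reference --c 0.99 --mu 1e-6 --N 100
-0.331059
```

and inverting it turns an observed multilocus mean F̄<sub>IS</sub> =
−0.083 from an exhaustively sampled population of 247 ramets into an
equilibrium clonality estimate:

```bash
$ fisdyn reference --invert -0.083 --mu 1e-6 --N 247
0.978126
```

— i.e. *c* ≈ 0.98 *if* the population were at equilibrium; the package's
transient analysis shows why such an estimate can be badly misleading
when the population is still converging.

The same things are available as a library:

```python
from fisdyn import (ModelParams, build_transition_matrix, propagate,
                    fis_summary, multilocus_sample_means, mean_signed_deviation)

params = ModelParams(N=100, n=2, c=0.99, mu=1e-6)
tm = build_transition_matrix(params)          # 5151 x 5151, column-stochastic
x50 = propagate((25, 50, 25), tm, 50, return_all=False)
print(fis_summary(x50, tm.space).mean)        # mean F_IS fifty generations
                                              # after a Hardy-Weinberg start
panels = multilocus_sample_means(x50, L=10, n_samples=100_000, seed=1,
                                 space=tm.space)
print(mean_signed_deviation(panels).max_magnitude)  # > 0.1: ten loci are
                                                    # not enough here
```

## Layout

| module | contents |
| --- | --- |
| `fisdyn.state_space` | state enumeration/indexing, per-state descriptors, start-state presets |
| `fisdyn.kernel` | mutation / gamete / reproduction maps, multinomial law, transition matrix |
| `fisdyn.chain` | propagation, steady state, mixing time, drift absorption, F_IS summaries |
| `fisdyn.timescales` | t_c, t_mu, the drift law fit, dominance map and phase diagram |
| `fisdyn.reference` | equilibrium closed form, clonality inversion, identity recursion |
| `fisdyn.sampling` | seeded Monte Carlo loci, multilocus panels, signed deviations |
| `fisdyn.tableio`, `fisdyn.pipeline`, `fisdyn.cli` | field-data F_IS helper, de Finetti export, configured runs, CLI |

See `docs/methods.md` for the modelling assumptions, numerical choices
and known limitations.
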