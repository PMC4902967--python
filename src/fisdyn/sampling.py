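"""Monte Carlo simulation of independent loci and multilocus F_IS sampling.

Two jobs live here.  First, a seeded forward simulator: many unlinked
loci, each an independent realisation of the genotype-frequency chain,
advanced one generation at a time by the deterministic
mutation-reproduction map followed by a multinomial draw of N
individuals.  This path has no state-space cap, so it covers parameter
ranges the exact chain cannot.

Second, the multilocus sampling analysis: the mean F_IS estimated from L
loci is the average of L i.i.d. per-locus values (unlinked loci,
exhaustive sampling of individuals), and its sampling error is summarised
by the mean *signed* deviation from the true mean — positive and negative
deviations averaged separately.  Loci at or near fixation (top allele
frequency above ``1 - sqrt(1/(2N))``) are excluded before sampling,
mirroring how such loci are dropped in empirical studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import StateDistribution
from .kernel import mutate, reproduce
from .state_space import (
    GenotypeState,
    ModelParams,
    StateSpace,
    as_counts,
    fis_from_counts,
)

__all__ = [
    "SimulationRun",
    "MultilocusSamples",
    "DeviationReport",
    "simulate",
    "multilocus_sample_means",
    "mean_signed_deviation",
]

#: Number of multilocus samples used by default for deviation analyses.
DEFAULT_N_SAMPLES = 100_000


@dataclass
class SimulationRun:
    """Trajectories of independent loci under one parameter set.

    ``trajectories[t, z]`` is the genotype count vector of locus ``z`` at
    generation ``t`` (shape ``(t_max + 1, n_loci, g)``).  Runs are
    bit-reproducible given ``(params, start, t_max, n_loci, seed)``.
    """

    params: ModelParams
    start: tuple[int, ...]
    t_max: int
    n_loci: int
    seed: int
    trajectories: np.ndarray

    def counts_at(self, t: int) -> np.ndarray:
        """(n_loci, g) genotype counts at generation t."""
        return self.trajectories[t]

    def fis_at(self, t: int):
        """Per-locus F_IS at generation t.

        Returns ``(fis, defined, near_fixed)``; ``fis`` is NaN where
        undefined (fixed loci).
        """
        _, _, _, fis, defined, _, near_fixed = fis_from_counts(self.counts_at(t), self.params)
        return fis, defined, near_fixed

    def summary_table(self) -> "pandas.DataFrame":  # noqa: F821
        """Per-generation summary over loci.

        Columns: t, mean_fis and var_fis over loci with defined F_IS,
        frac_fixed, frac_near_fixed.
        """
        import pandas as pd

        rows = []
        for t in range(self.t_max + 1):
            _, _, _, fis, defined, fixed, near_fixed = fis_from_counts(
                self.counts_at(t), self.params
            )
            ok = defined
            rows.append(
                {
                    "t": t,
                    "mean_fis": float(np.nanmean(fis)) if ok.any() else None,
                    "var_fis": float(np.nanvar(fis)) if ok.any() else None,
                    "frac_fixed": float(fixed.mean()),
                    "frac_near_fixed": float(near_fixed.mean()),
                }
            )
        return pd.DataFrame(rows)

    def tidy_table(self) -> "pandas.DataFrame":  # noqa: F821
        """Long-format export: one row per (locus, t) with counts and F_IS."""
        import pandas as pd

        from .state_space import genotype_labels

        labels = genotype_labels(self.params.n)
        T, L, g = self.trajectories.shape
        t_col = np.repeat(np.arange(T), L)
        locus_col = np.tile(np.arange(L), T)
        flat = self.trajectories.reshape(T * L, g)
        _, _, _, fis, defined, _, _ = fis_from_counts(flat, self.params)
        data = {"locus": locus_col, "t": t_col}
        for k, lab in enumerate(labels):
            data[f"q_{lab}"] = flat[:, k]
        data["fis"] = [float(v) if ok else None for v, ok in zip(fis, defined)]
        return pd.DataFrame(data)


def simulate(
    params: ModelParams,
    start: "GenotypeState | np.ndarray",
    t_max: int,
    n_loci: int,
    seed: int,
) -> SimulationRun:
    """Forward-simulate ``n_loci`` unlinked loci for ``t_max`` generations.

    Each generation applies the deterministic mutation + reproduction map
    to every locus's current frequencies and then draws the next counts
    from a multinomial of size N.  All loci share one generator stream
    (NumPy PCG64 seeded with ``seed``) and are advanced vectorised, one
    generation at a time, which keeps runs bit-reproducible for a fixed
    ``(seed, n_loci, t_max)``.
    """
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    q0 = as_counts(start)
    if q0.sum() != params.N or q0.shape[-1] != params.g:
        raise ValueError(
            f"start must hold N={params.N} individuals over g={params.g} genotypes"
        )
    rng = np.random.default_rng(seed)
    N = params.N
    traj = np.empty((t_max + 1, n_loci, params.g), dtype=np.int64)
    traj[0] = q0
    current = np.broadcast_to(q0, (n_loci, params.g)).astype(float)
    for t in range(1, t_max + 1):
        nu = reproduce(mutate(current / N, params), params)
        nu = np.clip(nu, 0.0, None)
        nu /= nu.sum(axis=1, keepdims=True)
        current = rng.multinomial(N, nu)
        traj[t] = current
    return SimulationRun(
        params=params,
        start=tuple(int(q) for q in q0),
        t_max=t_max,
        n_loci=n_loci,
        seed=seed,
        trajectories=traj,
    )


@dataclass(frozen=True)
class MultilocusSamples:
    """Sample means of F_IS over L-locus panels plus the exact target.

    ``true_mean`` is the mean of the conditional (non-near-fixed) source
    distribution the panels were drawn from; ``excluded_mass`` is the
    probability mass removed by the near-fixation rule.
    """

    means: np.ndarray
    true_mean: float
    L: int
    n_samples: int
    excluded_mass: float


def _source_values_weights(source, params, t=None):
    """Per-locus F_IS values, weights and near-fixation mask of a source."""
    if isinstance(source, SimulationRun):
        if t is None:
            raise ValueError("a SimulationRun source needs the generation t")
        fis, defined, near_fixed = source.fis_at(t)
        weights = np.full(len(fis), 1.0 / len(fis))
        return fis, weights, defined & ~near_fixed
    if isinstance(source, (StateDistribution, np.ndarray)):
        if params is None or not isinstance(params, StateSpace):
            raise ValueError("an exact-distribution source needs its StateSpace")
        space = params
        d = space.descriptors()
        probs = source.probs if isinstance(source, StateDistribution) else np.asarray(source)
        return d.fis, probs, d.defined & ~d.near_fixed
    raise TypeError(f"unsupported source type {type(source)!r}")


def multilocus_sample_means(
    source,
    L: int,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    space: StateSpace | None = None,
    t: int | None = None,
) -> MultilocusSamples:
    """Means of F_IS over repeated i.i.d. panels of L loci.

    ``source`` is either an exact :class:`~fisdyn.chain.StateDistribution`
    (pass its ``space``; loci are i.i.d. states) or a
    :class:`SimulationRun` snapshot (pass ``t``; loci are resampled from
    the replicate pool).  Near-fixed loci are excluded and the remaining
    distribution renormalised before drawing; sampling loci independently
    encodes the absence of linkage between them.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    vals, weights, keep = _source_values_weights(source, space, t)
    w = np.where(keep, weights, 0.0)
    W = float(w.sum())
    if W <= 0.0:
        raise ValueError("source distribution is entirely (near-)fixed; nothing to sample")
    p = w / W
    kept = p > 0
    v, p = vals[kept], p[kept]
    true_mean = float(np.dot(v, p))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(v), size=(n_samples, L), p=p)
    means = v[idx].mean(axis=1)
    return MultilocusSamples(
        means=means,
        true_mean=true_mean,
        L=L,
        n_samples=n_samples,
        excluded_mass=1.0 - W / float(np.sum(weights)),
    )


@dataclass(frozen=True)
class DeviationReport:
    """Mean signed deviation of sample means from the true mean.

    Positive and negative deviations are averaged separately:
    ``delta_plus`` over the ``z1`` samples at or above the true mean,
    ``delta_minus`` over the ``z2`` samples below it (``z1 + z2`` equals
    the number of samples).
    """

    delta_plus: float
    delta_minus: float
    z1: int
    z2: int
    L: int | None = None
    true_mean: float | None = None

    @property
    def max_magnitude(self) -> float:
        return max(abs(self.delta_plus), abs(self.delta_minus))

    def as_dict(self) -> dict:
        return {
            "delta_plus": self.delta_plus,
            "delta_minus": self.delta_minus,
            "z1": self.z1,
            "z2": self.z2,
            "L": self.L,
            "true_mean": self.true_mean,
        }


def mean_signed_deviation(
    samples: "MultilocusSamples | np.ndarray",
    true_mean: float | None = None,
) -> DeviationReport:
    """Split the deviations of sample means around the true mean.

    Accepts either a :class:`MultilocusSamples` (its own ``true_mean`` is
    used) or a raw array of sample means plus an explicit ``true_mean``.
    A side with no samples reports a zero deviation.
    """
    if isinstance(samples, MultilocusSamples):
        means = samples.means
        target = samples.true_mean if true_mean is None else true_mean
        L = samples.L
    else:
        means = np.asarray(samples, dtype=float)
        if true_mean is None:
            raise ValueError("true_mean is required for a raw sample array")
        target = true_mean
        L = None
    if means.size == 0:
        raise ValueError("no sample means provided")
    dev = means - target
    pos = dev >= 0.0
    z1, z2 = int(pos.sum()), int((~pos).sum())
    delta_plus = float(dev[pos].mean()) if z1 else 0.0
    delta_minus = float(dev[~pos].mean()) if z2 else 0.0
    return DeviationReport(
        delta_plus=delta_plus,
        delta_minus=delta_minus,
        z1=z1,
        z2=z2,
        L=L,
        true_mean=target,
    )
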