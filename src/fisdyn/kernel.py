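"""One-generation transition law of the genotype-frequency Markov chain.

Each generation applies, in order:

1. **Mutation** — every allele copy independently keeps its identity with
   probability ``alpha = 1 - mu`` or mutates into one of the ``n - 1``
   other alleles with probability ``beta = mu/(n - 1)`` each (symmetric
   k-alleles / Jukes-Cantor scheme), giving frequencies ``nu_I``.
2. **Reproduction** — a fraction ``c`` of offspring copies the parental
   genotype (clonal), the remaining ``1 - c`` are drawn from random
   mating: Hardy-Weinberg proportions of the post-mutation gamete pool,
   ``nu_III = c * nu_I + (1 - c) * HWE(p_I)``.
3. **Genetic drift** — the next state is a multinomial draw of ``N``
   individuals from ``nu_III``.

The deterministic steps (1-2) map genotype frequencies to genotype
frequencies; step (3) turns the chain stochastic and yields the
state-to-state transition probabilities assembled in
:func:`build_transition_matrix`.

All deterministic maps accept arrays of shape ``(..., g)`` and operate on
the last axis, so the Monte Carlo simulator can push many loci through
them at once.

Matrix orientation
------------------
``TransitionMatrix.M`` is **column-stochastic**: column ``j`` holds the
distribution of the next state given current state ``j`` (most linear
algebra texts use the row convention; here distributions are column
vectors and propagate as ``x_{t+1} = M @ x_t``).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .state_space import (
    DEFAULT_STATE_CAP,
    GenotypeState,
    ModelParams,
    StateSpace,
    as_counts,
    enumerate_states,
    genotype_pairs,
)

__all__ = [
    "TransitionMatrix",
    "mutate",
    "gamete_frequencies",
    "reproduce",
    "step_deterministic",
    "transition_probability",
    "build_transition_matrix",
]

#: Frequencies more negative than this are treated as floating-point noise
#: and clamped to zero before multinomial use.
_NEG_CLAMP = -1e-15


@lru_cache(maxsize=None)
def _pair_structure(n: int):
    """Index helpers for the canonical genotype order, cached per n."""
    pairs = genotype_pairs(n)
    hom_pos = tuple(k for k, (i, j) in enumerate(pairs) if i == j)
    het_pos = tuple(k for k, (i, j) in enumerate(pairs) if i != j)
    return pairs, hom_pos, het_pos


def _hom_het_sums(nu: np.ndarray, n: int):
    """Per-allele homozygote frequencies and heterozygote involvement sums."""
    pairs, hom_pos, het_pos = _pair_structure(n)
    hom = nu[..., hom_pos]  # (..., n), allele order
    het_inv = np.zeros(nu.shape[:-1] + (n,))
    for k in het_pos:
        i, j = pairs[k]
        het_inv[..., i] += nu[..., k]
        het_inv[..., j] += nu[..., k]
    het_tot = nu[..., het_pos].sum(axis=-1) if het_pos else np.zeros(nu.shape[:-1])
    return hom, het_inv, het_tot


def mutate(nu: np.ndarray, params: ModelParams) -> np.ndarray:
    """Genotype frequencies after one round of symmetric k-alleles mutation.

    Both allele copies of each genotype mutate independently; the
    closed-form per-genotype update is:

    * homozygote ``ii``: ``a^2 nu_ii + a b (sum_j nu_ij) + b^2 (other
      homozygotes + heterozygotes not involving i)``
    * heterozygote ``ij``: ``(a^2 + b^2) nu_ij + 2 a b (nu_ii + nu_jj) +
      (a b + b^2) (heterozygotes sharing exactly one of i, j) + 2 b^2
      (genotypes disjoint from {i, j})``

    with ``a = alpha``, ``b = beta``.  Total frequency is conserved.
    """
    nu = np.asarray(nu, dtype=float)
    n = params.n
    a, b = params.alpha, params.beta
    pairs, _, _ = _pair_structure(n)
    hom, het_inv, het_tot = _hom_het_sums(nu, n)
    hom_tot = hom.sum(axis=-1)
    out = np.empty_like(nu)
    for k, (i, j) in enumerate(pairs):
        if i == j:
            out[..., k] = (
                a * a * nu[..., k]
                + a * b * het_inv[..., i]
                + b * b * ((hom_tot - hom[..., i]) + (het_tot - het_inv[..., i]))
            )
        else:
            cross = (het_inv[..., i] - nu[..., k]) + (het_inv[..., j] - nu[..., k])
            disjoint = (hom_tot - hom[..., i] - hom[..., j]) + (
                het_tot - het_inv[..., i] - het_inv[..., j] + nu[..., k]
            )
            out[..., k] = (
                (a * a + b * b) * nu[..., k]
                + 2.0 * a * b * (hom[..., i] + hom[..., j])
                + (a * b + b * b) * cross
                + 2.0 * b * b * disjoint
            )
    return out


def gamete_frequencies(nu: np.ndarray) -> np.ndarray:
    """Allele frequencies of the gamete pool: p_i = nu_ii + 0.5 sum_j nu_ij.

    Infers ``n`` from the genotype-vector length g = n(n+1)/2.
    """
    nu = np.asarray(nu, dtype=float)
    g = nu.shape[-1]
    n = int(round(((8 * g + 1) ** 0.5 - 1) / 2))  # invert g = n(n+1)/2
    hom, het_inv, _ = _hom_het_sums(nu, n)
    return hom + 0.5 * het_inv


def reproduce(nu: np.ndarray, params: ModelParams) -> np.ndarray:
    """Genotype frequencies after reproduction with clonal fraction ``c``.

    ``nu`` is the post-mutation vector; the sexual share lands on
    Hardy-Weinberg proportions of the gamete-pool allele frequencies.
    """
    nu = np.asarray(nu, dtype=float)
    c = params.c
    pairs, _, _ = _pair_structure(params.n)
    p = gamete_frequencies(nu)
    out = np.empty_like(nu)
    for k, (i, j) in enumerate(pairs):
        if i == j:
            hwe = p[..., i] ** 2
        else:
            hwe = 2.0 * p[..., i] * p[..., j]
        out[..., k] = c * nu[..., k] + (1.0 - c) * hwe
    return out


def step_deterministic(state: "GenotypeState | np.ndarray", params: ModelParams) -> np.ndarray:
    """Deterministic part of one generation: mutation then reproduction.

    Accepts a count vector (or batch of them) and returns ``nu_III``, the
    multinomial probability vector for the next generation's draw.
    """
    counts = np.asarray(as_counts(state) if not isinstance(state, np.ndarray) else state, dtype=float)
    nu = counts / counts.sum(axis=-1, keepdims=True)
    out = reproduce(mutate(nu, params), params)
    # clamp floating-point noise so the multinomial never sees p < 0
    return np.where((out > _NEG_CLAMP) & (out < 0.0), 0.0, out)


def _log_multinomial(counts: np.ndarray, nu: np.ndarray, N: int) -> np.ndarray:
    """Log multinomial pmf of count rows under probability vector nu.

    Computed via log-gamma so that N! never overflows.  Rows demanding an
    event of probability zero get -inf.
    """
    counts = np.atleast_2d(counts)
    logcoef = gammaln(N + 1) - gammaln(counts + 1).sum(axis=1)
    pos = nu > 0.0
    logp = logcoef + counts[:, pos] @ np.log(nu[pos])
    if not pos.all():
        impossible = (counts[:, ~pos] > 0).any(axis=1)
        logp = np.where(impossible, -np.inf, logp)
    return logp


def transition_probability(
    from_state: "GenotypeState | np.ndarray",
    to_state: "GenotypeState | np.ndarray",
    params: ModelParams,
) -> float:
    """One-generation probability of moving between two genotypic states.

    The multinomial pmf of ``to_state`` under ``nu_III(from_state)``,
    evaluated in log space.
    """
    q_from = as_counts(from_state)
    q_to = as_counts(to_state)
    if q_from.sum() != params.N or q_to.sum() != params.N:
        raise ValueError("both states must contain exactly N individuals")
    nu = step_deterministic(q_from, params)
    logp = _log_multinomial(q_to[None, :], nu, params.N)[0]
    return float(np.exp(logp))


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix over an enumerated state space."""

    M: np.ndarray
    space: StateSpace

    @property
    def params(self) -> ModelParams:
        return self.space.params

    def __len__(self) -> int:
        return self.M.shape[0]

    def cache_key(self) -> str:
        p = self.params
        return f"tm_N{p.N}_n{p.n}_c{p.c!r}_mu{p.mu!r}.npz"

    def save(self, directory: "str | Path") -> "Path":  # noqa: F821
        """Cache the dense matrix as a compressed npz keyed by (N, n, c, mu)."""
        from pathlib import Path

        path = Path(directory) / self.cache_key()
        np.savez_compressed(path, M=self.M)
        return path

    @classmethod
    def load(cls, params: ModelParams, directory: "str | Path", cap: int = DEFAULT_STATE_CAP):
        """Load a cached matrix for these parameters, or None if absent."""
        from pathlib import Path

        space = enumerate_states(params, cap=cap)
        probe = cls(M=np.empty((0, 0)), space=space)
        path = Path(directory) / probe.cache_key()
        if not path.exists():
            return None
        with np.load(path) as data:
            return cls(M=data["M"], space=space)

    def to_table(self, threshold: float = 0.0) -> "pandas.DataFrame":  # noqa: F821
        """Sparse tabular export: (state_index_from, state_index_to, probability)."""
        import pandas as pd

        to_idx, from_idx = np.nonzero(self.M > threshold)
        return pd.DataFrame(
            {
                "state_index_from": from_idx,
                "state_index_to": to_idx,
                "probability": self.M[to_idx, from_idx],
            }
        ).sort_values(["state_index_from", "state_index_to"], ignore_index=True)


def build_transition_matrix(
    params: ModelParams,
    space: StateSpace | None = None,
    cap: int = DEFAULT_STATE_CAP,
) -> TransitionMatrix:
    """Assemble the full transition matrix (current state per column).

    Column ``j`` is the multinomial pmf over all states induced by
    ``nu_III`` of state ``j``; every column sums to one.
    """
    if space is None:
        space = enumerate_states(params, cap=cap)
    states = space.states
    S = states.shape[0]
    N = params.N
    logcoef = gammaln(N + 1) - gammaln(states + 1).sum(axis=1)
    M = np.empty((S, S))
    for j in range(S):
        nu = step_deterministic(states[j], params)
        pos = nu > 0.0
        logp = logcoef + states[:, pos] @ np.log(nu[pos])
        p = np.exp(logp)
        if not pos.all():
            p[(states[:, ~pos] > 0).any(axis=1)] = 0.0
        M[:, j] = p
    return TransitionMatrix(M=M, space=space)
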