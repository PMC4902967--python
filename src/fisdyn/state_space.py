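"""Genotypic state space of one locus in a finite diploid population.

The population is a fixed number ``N`` of diploid individuals (ramets)
observed at a single locus carrying ``n`` possible alleles.  With
unordered genotypes there are ``g = n(n+1)/2`` genotype classes, and the
population's *genotypic state* is the vector of counts of individuals per
genotype, summing to ``N``.  These count vectors are the states of the
Markov chain built in :mod:`fisdyn.kernel`; this module enumerates and
indexes them and computes per-state descriptors (allele frequencies,
observed and expected heterozygosity, the inbreeding coefficient
``F_IS = (H_e - H_o)/H_e`` and fixation flags).

Conventions
-----------
* Genotype order is lexicographic over allele pairs ``(i, j)`` with
  ``i <= j``: ``A1A1, A1A2, ..., A1An, A2A2, A2A3, ..., AnAn``.  For two
  alleles this reads ``(aa, aA, AA)``.
* State order is colexicographic over the count vector (the count of the
  last genotype varies slowest), which makes indices deterministic and
  cache-friendly.
* ``F_IS`` is undefined when ``H_e = 0`` (a single allele left, i.e. the
  locus is fixed); descriptors carry an explicit ``None`` sentinel rather
  than a NaN in that case.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "GenotypeState",
    "FisRecord",
    "StateSpace",
    "StateSpaceTooLargeError",
    "StartFis",
    "DEFAULT_STATE_CAP",
    "genotype_pairs",
    "genotype_labels",
    "count_states",
    "enumerate_states",
    "describe_state",
    "fis_from_counts",
    "near_fixation_threshold",
    "preset_start",
    "space_table",
]

#: Default refusal threshold for exact state-space enumeration.  Larger
#: systems are meant for the Monte Carlo path in :mod:`fisdyn.sampling`.
DEFAULT_STATE_CAP = 2_000_000


@lru_cache(maxsize=None)
def genotype_pairs(n: int) -> tuple[tuple[int, int], ...]:
    """Canonical genotype order: allele pairs (i, j), i <= j, 0-based."""
    return tuple((i, j) for i in range(n) for j in range(i, n))


@lru_cache(maxsize=None)
def genotype_labels(n: int) -> tuple[str, ...]:
    """Human-readable genotype labels (``A1A1``, ``A1A2``, ...)."""
    return tuple(f"A{i + 1}A{j + 1}" for i, j in genotype_pairs(n))


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the one-locus model.

    Parameters
    ----------
    N : int
        Population size (number of ramets), ``>= 1``.
    n : int
        Number of alleles at the locus, ``>= 2``.
    c : float
        Rate of clonality: the proportion of offspring per generation
        produced clonally, in ``[0, 1]``.  The remaining ``1 - c`` derive
        from random mating (including selfing at rate ``1/N``).
    mu : float
        Per-generation, per-allele-copy mutation rate of the symmetric
        k-alleles (Jukes-Cantor type) scheme, in ``[0, (n-1)/n]``.
    """

    N: int
    n: int = 2
    c: float = 0.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int, np.integer)) and self.N >= 1):
            raise ValueError(f"N must be a positive integer, got {self.N!r}")
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 2):
            raise ValueError(f"n must be an integer >= 2, got {self.n!r}")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"clonality rate c must lie in [0, 1], got {self.c!r}")
        if not 0.0 <= self.mu <= (self.n - 1) / self.n:
            raise ValueError(
                f"mutation rate mu must lie in [0, (n-1)/n] = [0, {(self.n - 1) / self.n}], "
                f"got {self.mu!r}"
            )

    @property
    def g(self) -> int:
        """Number of unordered genotypes, n(n+1)/2."""
        return self.n * (self.n + 1) // 2

    @property
    def alpha(self) -> float:
        """Probability that an allele copy does not mutate in one generation."""
        return 1.0 - self.mu

    @property
    def beta(self) -> float:
        """Probability of mutating into one specific other allele, mu/(n-1)."""
        return self.mu / (self.n - 1)


@dataclass(frozen=True)
class GenotypeState:
    """Counts of individuals per genotype (canonical order), summing to N."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(q < 0 for q in self.counts):
            raise ValueError(f"genotype counts must be non-negative, got {self.counts}")

    @property
    def N(self) -> int:
        return int(sum(self.counts))

    def frequencies(self) -> np.ndarray:
        """Genotype frequencies nu = q / N."""
        q = np.asarray(self.counts, dtype=float)
        return q / q.sum()


def as_counts(state: "GenotypeState | Sequence[int] | np.ndarray") -> np.ndarray:
    """Coerce a state-like object to an integer count vector."""
    if isinstance(state, GenotypeState):
        return np.asarray(state.counts, dtype=np.int64)
    return np.asarray(state, dtype=np.int64)


def count_states(N: int, n: int) -> int:
    """Exact number of genotypic states: C(N + g - 1, g - 1) with g = n(n+1)/2.

    This is the number of ways to distribute ``N`` indistinguishable
    individuals over the ``g`` genotype classes (compositions of N into g
    non-negative parts).  Computed with exact integer arithmetic.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if n < 2:
        raise ValueError("n must be >= 2")
    g = n * (n + 1) // 2
    return math.comb(N + g - 1, g - 1)


class StateSpaceTooLargeError(ValueError):
    """Raised when exact enumeration would exceed the configured cap."""

    def __init__(self, count: int, cap: int):
        self.count = count
        self.cap = cap
        super().__init__(
            f"state space too large for exact enumeration: {count} states "
            f"exceed the cap of {cap}; use the Monte Carlo module "
            f"(fisdyn.sampling) for this parameter range"
        )


def _compositions(total: int, parts: int) -> Iterator[tuple[int, ...]]:
    """All compositions of `total` into `parts` non-negative parts, colex order."""
    if parts == 1:
        yield (total,)
        return
    for last in range(total + 1):
        for head in _compositions(total - last, parts - 1):
            yield head + (last,)


@dataclass
class StateSpace:
    """Enumerated genotypic state space with stable integer indexing."""

    params: ModelParams
    states: np.ndarray  # (S, g) int64, row s = counts of state s
    _index: dict[tuple[int, ...], int] = field(repr=False)
    _descriptors: "StateDescriptors | None" = field(default=None, repr=False)

    def __len__(self) -> int:
        return self.states.shape[0]

    def __iter__(self) -> Iterator[GenotypeState]:
        for row in self.states:
            yield GenotypeState(tuple(int(q) for q in row))

    def state(self, index: int) -> GenotypeState:
        return GenotypeState(tuple(int(q) for q in self.states[index]))

    def index_of(self, state: "GenotypeState | Sequence[int]") -> int:
        key = tuple(int(q) for q in as_counts(state))
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"{key} is not a valid state for N={self.params.N}, n={self.params.n}")

    def point_mass(self, state: "GenotypeState | Sequence[int]") -> np.ndarray:
        """Probability vector concentrated on one state."""
        x = np.zeros(len(self))
        x[self.index_of(state)] = 1.0
        return x

    def descriptors(self) -> "StateDescriptors":
        """Vectorised per-state descriptors, computed once and cached."""
        if self._descriptors is None:
            self._descriptors = _compute_descriptors(self.states, self.params)
        return self._descriptors


@dataclass(frozen=True)
class StateDescriptors:
    """Arrays of per-state summaries over a whole state space.

    ``fis`` holds NaN where F_IS is undefined (fixation); use ``defined``
    to mask.  ``fixed`` flags single-allele states; ``near_fixed`` flags
    states where the top allele frequency exceeds ``1 - sqrt(1/(2N))``
    (fixed states included).
    """

    p: np.ndarray  # (S, n) allele frequencies
    Ho: np.ndarray  # (S,)
    He: np.ndarray  # (S,)
    fis: np.ndarray  # (S,), NaN where undefined
    defined: np.ndarray  # (S,) bool
    fixed: np.ndarray  # (S,) bool
    near_fixed: np.ndarray  # (S,) bool


def near_fixation_threshold(N: int) -> float:
    """Allele-frequency threshold 1 - sqrt(1/(2N)) above which a locus counts
    as near-fixed (and is excluded from multilocus F_IS sampling)."""
    return 1.0 - math.sqrt(1.0 / (2.0 * N))


def fis_from_counts(counts: np.ndarray, params: ModelParams):
    """Vectorised descriptor computation for count arrays of shape (..., g).

    Returns ``(p, Ho, He, fis, defined, fixed, near_fixed)`` with leading
    shape broadcast from ``counts``; ``fis`` is NaN where undefined.
    """
    counts = np.asarray(counts, dtype=float)
    n = params.n
    pairs = genotype_pairs(n)
    N = counts.sum(axis=-1, keepdims=True)
    nu = counts / N
    p = np.zeros(counts.shape[:-1] + (n,))
    Ho = np.zeros(counts.shape[:-1])
    for k, (i, j) in enumerate(pairs):
        if i == j:
            p[..., i] += nu[..., k]
        else:
            p[..., i] += 0.5 * nu[..., k]
            p[..., j] += 0.5 * nu[..., k]
            Ho += nu[..., k]
    He = 1.0 - (p**2).sum(axis=-1)
    # fixation: a single allele left <=> He == 0 <=> max p == 1
    fixed = np.isclose(He, 0.0, atol=1e-12)
    defined = ~fixed
    with np.errstate(divide="ignore", invalid="ignore"):
        fis = np.where(defined, (He - Ho) / np.where(defined, He, 1.0), np.nan)
    near_fixed = p.max(axis=-1) > near_fixation_threshold(params.N)
    near_fixed |= fixed  # guard against threshold rounding at tiny N
    return p, Ho, He, fis, defined, fixed, near_fixed


def _compute_descriptors(states: np.ndarray, params: ModelParams) -> StateDescriptors:
    p, Ho, He, fis, defined, fixed, near_fixed = fis_from_counts(states, params)
    return StateDescriptors(p=p, Ho=Ho, He=He, fis=fis, defined=defined, fixed=fixed, near_fixed=near_fixed)


def enumerate_states(params: ModelParams, cap: int = DEFAULT_STATE_CAP) -> StateSpace:
    """Enumerate all genotypic states in canonical (colexicographic) order.

    Raises :class:`StateSpaceTooLargeError` (carrying the exact count) when
    the space exceeds ``cap``.
    """
    total = count_states(params.N, params.n)
    if total > cap:
        raise StateSpaceTooLargeError(total, cap)
    states = np.array(list(_compositions(params.N, params.g)), dtype=np.int64)
    index = {tuple(int(q) for q in row): i for i, row in enumerate(states)}
    return StateSpace(params=params, states=states, _index=index)


@dataclass(frozen=True)
class FisRecord:
    """Per-state summary: heterozygosities, F_IS and fixation flags."""

    p: tuple[float, ...]
    Ho: float
    He: float
    fis: float | None  # None = undefined (fixation)
    fixed: bool
    near_fixed: bool


def describe_state(state: "GenotypeState | Sequence[int]", params: ModelParams) -> FisRecord:
    """Allele frequencies, H_o, H_e, F_IS and fixation flags for one state.

    F_IS = (H_e - H_o)/H_e; when H_e = 0 (one allele left) it is undefined
    and reported as ``None``, never as a NaN.
    """
    counts = as_counts(state)
    if counts.sum() != params.N:
        raise ValueError(f"counts sum to {counts.sum()}, expected N={params.N}")
    if counts.shape[-1] != params.g:
        raise ValueError(f"expected {params.g} genotype counts, got {counts.shape[-1]}")
    p, Ho, He, fis, defined, fixed, near_fixed = fis_from_counts(counts, params)
    return FisRecord(
        p=tuple(float(v) for v in p),
        Ho=float(Ho),
        He=float(He),
        fis=float(fis) if defined else None,
        fixed=bool(fixed),
        near_fixed=bool(near_fixed),
    )


class StartFis(Enum):
    """Named start states under isoplethy (equal allele frequencies 1/n)."""

    FIS_MINUS1 = "fis-1"  # complete heterozygosity
    FIS_ZERO = "fis0"  # Hardy-Weinberg proportions
    FIS_PLUS1 = "fis+1"  # complete homozygosity


def _round_targets(targets: np.ndarray, N: int, het_mask: np.ndarray) -> np.ndarray:
    """Largest-remainder rounding of real-valued genotype count targets.

    Remainder individuals go to heterozygote classes first (then by
    fractional part, then by index) so that rounding never creates a
    spurious homozygote excess.
    """
    floor = np.floor(targets).astype(np.int64)
    remainder = int(N - floor.sum())
    frac = targets - floor
    order = sorted(
        range(len(targets)),
        key=lambda k: (not het_mask[k], -frac[k], k),
    )
    out = floor.copy()
    for k in order[:remainder]:
        out[k] += 1
    return out


def preset_start(params: ModelParams, label: "StartFis | str") -> GenotypeState:
    """Isoplethic start states with F_IS equal to -1, 0 or +1.

    For two alleles: ``FIS_MINUS1 -> (0, N, 0)``, ``FIS_ZERO -> (N/4, N/2,
    N/4)``, ``FIS_PLUS1 -> (N/2, 0, N/2)``; general ``n`` uses equal allele
    frequencies ``1/n``.  When the exact target counts are not integers the
    nearest state is used (remainders distributed to heterozygote classes
    first) and a warning is emitted.
    """
    if isinstance(label, str):
        label = StartFis(label)
    n, N = params.n, params.N
    pairs = genotype_pairs(n)
    het_mask = np.array([i != j for i, j in pairs])
    targets = np.zeros(params.g)
    if label is StartFis.FIS_ZERO:
        for k, (i, j) in enumerate(pairs):
            targets[k] = N / n**2 if i == j else 2.0 * N / n**2
    elif label is StartFis.FIS_PLUS1:
        targets[~het_mask] = N / n
    elif label is StartFis.FIS_MINUS1:
        n_het = n * (n - 1) // 2
        targets[het_mask] = N / n_het
    counts = _round_targets(targets, N, het_mask)
    if not np.allclose(targets, counts):
        warnings.warn(
            f"exact isoplethic start {label.value} impossible for N={N}, n={n}; "
            f"using nearest state {tuple(int(q) for q in counts)}",
            stacklevel=2,
        )
    return GenotypeState(tuple(int(q) for q in counts))


def space_table(space: StateSpace) -> "pandas.DataFrame":  # noqa: F821
    """Tabular export of the state space with per-state descriptors.

    Columns: ``state_index``, one ``q_<label>`` per genotype, one
    ``p_A<i>`` per allele, ``Ho``, ``He``, ``fis`` (empty where
    undefined), ``fixed``, ``near_fixed``.
    """
    import pandas as pd

    params = space.params
    d = space.descriptors()
    data: dict[str, object] = {"state_index": np.arange(len(space))}
    for k, lab in enumerate(genotype_labels(params.n)):
        data[f"q_{lab}"] = space.states[:, k]
    for i in range(params.n):
        data[f"p_A{i + 1}"] = d.p[:, i]
    data["Ho"] = d.Ho
    data["He"] = d.He
    data["fis"] = [float(v) if ok else None for v, ok in zip(d.fis, d.defined)]
    data["fixed"] = d.fixed
    data["near_fixed"] = d.near_fixed
    return pd.DataFrame(data)
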