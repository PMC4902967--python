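"""Equilibrium reference model for mean F_IS under partial clonality.

A classical infinite-alleles treatment of a single finite population with
clonal fraction ``c``, mutation rate ``mu`` and size ``N`` (selfing at the
random-mating rate ``1/N``) yields a closed-form equilibrium mean

    mean F_IS = 1 / ((2N - 1) - 2N / (c * gamma)),   gamma = (1 - mu)^2,

negative for all ``c`` in (0, 1] and approaching -1 as ``c -> 1`` with
``mu -> 0`` in small populations.  The same model gives an affine
two-variable recursion for the allele identities ``F`` (within
individuals, ``1 - H_o``) and ``Theta`` (within the population,
``1 - H_e``), whose fixed point reproduces the closed form and whose
iteration yields a convergence time for the mean.

Because these formulas assume infinitely many alleles and treat
heterozygosity as continuous, they can disagree with the exact
finite-allele chain of :mod:`fisdyn.chain` where mutation is strong: at
``c = 1, mu = 1e-2, N = 100`` the closed form gives about -0.20 while the
two-allele chain's steady mean is about -0.02.  That discrepancy is a
property of the models, not a defect of either implementation.

The closed form also inverts algebraically, turning an observed
multilocus mean F_IS from an exhaustively sampled population into an
equilibrium estimate of the clonality rate ``c``.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BallouxPair",
    "equilibrium_mean_fis",
    "invert_for_c",
    "recursion_step",
    "recursion_fixed_point",
    "recursion_convergence_time",
    "pair_from_heterozygosities",
]


@dataclass(frozen=True)
class BallouxPair:
    """Allele identities (F, Theta) = (1 - H_o, 1 - H_e)."""

    F: float
    Theta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.F <= 1.0 and 0.0 <= self.Theta <= 1.0):
            raise ValueError(f"identities must lie in [0, 1], got {self}")

    @property
    def fis(self) -> float | None:
        """F_IS = (F - Theta)/(1 - Theta); None when Theta = 1 (H_e = 0)."""
        if self.Theta >= 1.0:
            return None
        return (self.F - self.Theta) / (1.0 - self.Theta)


def pair_from_heterozygosities(Ho: float, He: float) -> BallouxPair:
    """Build an identity pair from observed and expected heterozygosity."""
    return BallouxPair(F=1.0 - Ho, Theta=1.0 - He)


def _metapopulation_mean_fis(
    c: float, mu: float, N: int, q_s: float = 1.0, q_d: float = 0.0
) -> float:
    """General metapopulation form of the equilibrium mean F_IS.

    ``q_s``/``q_d`` are the probabilities that two individuals sampled in
    the same/different subpopulations after migration were sired in the
    same subpopulation one generation earlier.  Only the single-population
    specialisation ``q_s = 1, q_d = 0`` is exposed publicly; this general
    form is kept as an internal cross-check (it reduces to
    :func:`equilibrium_mean_fis` in that limit, for mu > 0).
    """
    g = (1.0 - mu) ** 2
    num = g * (q_s - c * (g * (q_s - q_d) - 1.0) - 1.0)
    den = 2.0 * N * (1.0 - g * c) * (g * (q_s - q_d) - 1.0) - num
    return num / den


def equilibrium_mean_fis(c: float, mu: float, N: int) -> float:
    """Equilibrium mean F_IS of a single partially clonal population.

    ``1 / ((2N - 1) - 2N/(c*(1 - mu)^2))``.  At ``c = 0`` the expression's
    limit is 0 (random mating: Hardy-Weinberg), returned directly with a
    warning.  Always <= 0 for ``c`` in (0, 1]; tends to 0 from below as N
    grows and to -1 at full clonality with mu -> 0.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"c must lie in [0, 1], got {c}")
    if c == 0.0:
        warnings.warn(
            "equilibrium mean F_IS at c=0 is the limit value 0 (Hardy-Weinberg)",
            stacklevel=2,
        )
        return 0.0
    gamma = (1.0 - mu) ** 2
    return 1.0 / ((2.0 * N - 1.0) - 2.0 * N / (c * gamma))


def invert_for_c(observed_mean_fis: float, mu: float, N: int) -> float:
    """Clonality rate implied by an observed equilibrium mean F_IS.

    Algebraic inversion ``c = 2N / (gamma * ((2N - 1) - 1/Fbar))``.  The
    equilibrium model only produces negative means, so ``Fbar >= 0`` is
    rejected; a result marginally above 1 (possible when ``Fbar`` is near
    -1 with ``mu > 0``) is clipped to 1 with a warning.
    """
    fbar = observed_mean_fis
    if fbar >= 0.0:
        raise ValueError(
            f"observed mean F_IS must be negative to be consistent with the "
            f"equilibrium model, got {fbar}"
        )
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    gamma = (1.0 - mu) ** 2
    c = 2.0 * N / (gamma * ((2.0 * N - 1.0) - 1.0 / fbar))
    if c <= 0.0:
        raise ValueError(
            f"observed mean F_IS = {fbar} is inconsistent with the equilibrium "
            f"model for N={N}, mu={mu} (implied c = {c})"
        )
    if c > 1.0:
        warnings.warn(
            f"implied clonality rate {c:.6f} exceeds 1; clipping to 1.0",
            stacklevel=2,
        )
        c = 1.0
    return c


def _recursion_terms(c: float, mu: float, N: int):
    gamma = (1.0 - mu) ** 2
    A = np.array(
        [
            [c + (1.0 - c) / (2.0 * N), (1.0 - c) * (1.0 - 1.0 / N)],
            [1.0 / (2.0 * N), 1.0 - 1.0 / N],
        ]
    )
    # Constant terms: a sexual offspring selfs with probability 1/N and then
    # carries identity (1 + F)/2, contributing (1-c)/(2N); the population
    # identity gains 1/(2N) from sampling the same parent twice.  Any other
    # constant in the first slot pushes the identities above 1 and breaks
    # agreement with the closed-form equilibrium.
    b = np.array([(1.0 - c) / (2.0 * N), 1.0 / (2.0 * N)])
    return gamma, A, b


def recursion_step(pair: BallouxPair, c: float, mu: float, N: int) -> BallouxPair:
    """One iteration of the affine identity recursion.

    ``(F, Theta)_{t+1} = gamma * (A @ (F, Theta)_t + b)`` with the 2x2
    coefficient matrix in ``c`` and ``N``; its fixed point's F_IS equals
    the closed-form equilibrium mean.
    """
    gamma, A, b = _recursion_terms(c, mu, N)
    F, Theta = gamma * (A @ np.array([pair.F, pair.Theta]) + b)
    return BallouxPair(F=float(F), Theta=float(Theta))


def recursion_fixed_point(c: float, mu: float, N: int) -> BallouxPair:
    """Fixed point of the recursion from the 2x2 linear solve
    ``(I - gamma*A) x = gamma*b``."""
    gamma, A, b = _recursion_terms(c, mu, N)
    x = np.linalg.solve(np.eye(2) - gamma * A, gamma * b)
    return BallouxPair(F=float(np.clip(x[0], 0.0, 1.0)), Theta=float(np.clip(x[1], 0.0, 1.0)))


def recursion_convergence_time(
    start: BallouxPair,
    c: float,
    mu: float,
    N: int,
    epsilon: float | None = None,
    max_iterations: int = 100_000_000,
) -> int:
    """Generations until the recursion's F_IS is within epsilon of its limit.

    The smallest ``t`` with ``|fis_t - fis_inf| < epsilon`` when iterating
    from ``start`` (default epsilon: 1/(2N)).  The target comes from the
    exact fixed point, so a start already at equilibrium returns 0.
    """
    eps = 1.0 / (2.0 * N) if epsilon is None else epsilon
    target = recursion_fixed_point(c, mu, N).fis
    if target is None:
        raise ValueError("fixed point has He = 0; convergence time undefined")
    pair = start
    for t in range(max_iterations + 1):
        fis = pair.fis
        if fis is not None and abs(fis - target) < eps:
            return t
        pair = recursion_step(pair, c, mu, N)
    raise RuntimeError(
        f"recursion did not converge within {max_iterations} iterations "
        f"(|fis - target| = {abs(pair.fis - target):.3g})"
    )
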