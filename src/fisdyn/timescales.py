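"""Closed-form convergence times and the dominant-process map.

Each evolutionary force acting alone drives the genotype frequencies to
its own steady state at its own speed.  With an acceptable error
``epsilon`` (default ``1/(2N)``), the maximal convergence times are

* reproduction: ``t_c = 1 + log(eps)/log(c)`` — one generation at full
  sexuality (``c = 0``, random mating reaches Hardy-Weinberg immediately)
  and infinite at full clonality;
* mutation: ``t_mu = 1 + log(eps)/log(1 - mu*n/(n-1))`` — the k-alleles
  scheme decays deviations from equal allele frequencies and F_IS = 0
  geometrically with factor ``1 - mu*n/(n-1)``;
* drift: ``t_N ~= sigma*N - tau``, an empirically linear law whose slope
  ``sigma`` grows with the number of alleles; ``sigma`` and ``tau`` are
  fitted from exact absorption times (:func:`fisdyn.chain.absorption_profile`).

The smallest of the three identifies the process that dominates the
genotype-frequency dynamics; pairwise equality of the closed forms gives
the boundary curves that partition (c, mu, N) space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

from .chain import absorption_profile
from .state_space import DEFAULT_STATE_CAP, ModelParams

__all__ = [
    "DriftFit",
    "TimescaleReport",
    "t_c",
    "t_mu",
    "default_epsilon",
    "ceil_generations",
    "fit_drift_law",
    "default_drift_fit",
    "dominant_process",
    "clonality_mutation_boundary",
    "clonality_drift_boundary",
    "mutation_drift_boundary",
    "phase_diagram",
]


def default_epsilon(N: int) -> float:
    """Acceptable error 1/(2N): half the minimal resolvable frequency change."""
    return 1.0 / (2.0 * N)


def _check_epsilon(epsilon: float) -> None:
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon must lie in (0, 1), got {epsilon}")


def t_c(c: float, epsilon: float) -> float:
    """Maximal convergence time of reproduction alone (generations, real).

    ``1 + log(eps)/log(c)``; equals 1 at c = 0 and diverges as c -> 1.
    The residual deviation from Hardy-Weinberg shrinks by a factor c per
    generation, hence the geometric-progression form.
    """
    _check_epsilon(epsilon)
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"c must lie in [0, 1], got {c}")
    if c == 0.0:
        return 1.0
    if c == 1.0:
        return math.inf
    return 1.0 + math.log(epsilon) / math.log(c)


def t_mu(mu: float, n: int = 2, epsilon: float = 0.005) -> float:
    """Maximal convergence time of mutation alone (generations, real).

    Geometric decay with base ``1 - mu*n/(n-1)`` (for two alleles,
    ``1 - 2*mu``).  At the theoretical maximum ``mu = (n-1)/n`` the base is
    zero and convergence takes a single generation.
    """
    _check_epsilon(epsilon)
    if mu <= 0.0:
        raise ValueError(f"t_mu requires mu > 0, got {mu}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    base = 1.0 - mu * n / (n - 1)
    if base < 0.0:
        raise ValueError(f"mu={mu} exceeds the maximum (n-1)/n={(n - 1) / n}")
    if base == 0.0:
        return 1.0
    return 1.0 + math.log(epsilon) / math.log(base)


def ceil_generations(t: float) -> "int | float":
    """Integer reporting convention: ceiling of the real-valued time.

    Printed convergence times elsewhere occasionally differ by one
    generation from this convention; +-1 should be treated as equivalent.
    """
    return t if math.isinf(t) else math.ceil(t)


@dataclass(frozen=True)
class DriftFit:
    """Linear drift law t_N = sigma*N - tau fitted to absorption times."""

    sigma: float
    tau: float
    n: int
    N_grid: tuple[int, ...]

    def t_N(self, N: int) -> float:
        return self.sigma * N - self.tau


def fit_drift_law(
    n: int,
    N_grid: Sequence[int],
    cap: int = DEFAULT_STATE_CAP,
) -> DriftFit:
    """Fit ``t_N = sigma*N - tau`` through exact drift-absorption times.

    For each N on the grid the drift-only chain (c=1, mu=0) is built and
    the maximal expected time to genotypic uniformity extracted; a
    least-squares line through the (N, t_N) points gives sigma and tau.
    """
    N_grid = tuple(sorted(int(N) for N in N_grid))
    if len(N_grid) < 3:
        raise ValueError("need at least 3 grid points to fit the drift law")
    times = []
    for N in N_grid:
        prof = absorption_profile(ModelParams(N=N, n=n, c=1.0, mu=0.0), cap=cap)
        times.append(prof.t_N)
    slope, intercept = np.polyfit(np.asarray(N_grid, dtype=float), np.asarray(times), 1)
    return DriftFit(sigma=float(slope), tau=float(-intercept), n=n, N_grid=N_grid)


@lru_cache(maxsize=None)
def default_drift_fit(n: int = 2) -> DriftFit:
    """Drift-law fit on a standard grid, cached per allele count.

    The grid tops out at N = 60 (1891 exact states for two alleles) so the
    fit stays interactive; the law is linear enough that extrapolation to
    N of a few hundred is accurate to a few percent.
    """
    return fit_drift_law(n, range(10, 61, 10))


@dataclass(frozen=True)
class TimescaleReport:
    """The three per-process convergence times and the winner."""

    t_c: float
    t_mu: float
    t_N: float
    dominant: str  # 'reproduction' | 'mutation' | 'drift'
    epsilon: float
    params: ModelParams

    def as_dict(self) -> dict:
        return {
            "N": self.params.N,
            "n": self.params.n,
            "c": self.params.c,
            "mu": self.params.mu,
            "epsilon": self.epsilon,
            "t_c": self.t_c,
            "t_mu": self.t_mu,
            "t_N": self.t_N,
            "dominant": self.dominant,
        }


def dominant_process(
    params: ModelParams,
    fit: DriftFit | None = None,
    epsilon: float | None = None,
    t_N: float | None = None,
) -> TimescaleReport:
    """Which force governs the genotype dynamics at one parameter point.

    Computes t_c, t_mu and t_N (the latter from ``t_N`` if given, else
    from ``fit``, else from the cached default fit) and returns the argmin.
    ``mu = 0`` makes the mutation timescale infinite.
    """
    eps = default_epsilon(params.N) if epsilon is None else epsilon
    tc = t_c(params.c, eps)
    tm = t_mu(params.mu, params.n, eps) if params.mu > 0 else math.inf
    if t_N is None:
        fit = fit or default_drift_fit(params.n)
        t_N = fit.t_N(params.N)
    times = {"reproduction": tc, "mutation": tm, "drift": t_N}
    dominant = min(times, key=times.get)
    return TimescaleReport(t_c=tc, t_mu=tm, t_N=t_N, dominant=dominant, epsilon=eps, params=params)


def clonality_mutation_boundary(mu: float, n: int = 2) -> float:
    """c at which t_c = t_mu: c = 1 - mu*n/(n-1) (equal geometric bases)."""
    return 1.0 - mu * n / (n - 1)


def clonality_drift_boundary(t_N: float, epsilon: float) -> float:
    """c at which t_c = t_N: c = epsilon^(1/(t_N - 1))."""
    _check_epsilon(epsilon)
    if t_N <= 1.0:
        raise ValueError("drift time must exceed one generation")
    return epsilon ** (1.0 / (t_N - 1.0))


def mutation_drift_boundary(t_N: float, epsilon: float, n: int = 2) -> float:
    """mu at which t_mu = t_N: mu = (n-1)/n * (1 - epsilon^(1/(t_N - 1)))."""
    return (n - 1) / n * (1.0 - clonality_drift_boundary(t_N, epsilon))


def phase_diagram(
    N: int,
    n: int = 2,
    fit: DriftFit | None = None,
    epsilon: float | None = None,
    c_grid: Sequence[float] | None = None,
    mu_grid: Sequence[float] | None = None,
) -> "pandas.DataFrame":  # noqa: F821
    """Dominance labels over a (c, mu) grid for fixed N and n.

    Defaults: 41 clonality values linear on [0, 1] and 41 mutation rates
    log-spaced on [1e-9, (n-1)/n].
    """
    import pandas as pd

    fit = fit or default_drift_fit(n)
    tN = fit.t_N(N)
    if c_grid is None:
        c_grid = np.linspace(0.0, 1.0, 41)
    if mu_grid is None:
        mu_grid = np.logspace(-9, np.log10((n - 1) / n), 41)
    rows = []
    for c in c_grid:
        for mu in mu_grid:
            rep = dominant_process(
                ModelParams(N=N, n=n, c=float(c), mu=float(mu)),
                epsilon=epsilon,
                t_N=tN,
            )
            rows.append(
                {"c": float(c), "mu": float(mu), "t_c": rep.t_c, "t_mu": rep.t_mu,
                 "t_N": rep.t_N, "dominant": rep.dominant}
            )
    return pd.DataFrame(rows)
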