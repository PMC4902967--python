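"""Exact analysis of the genotype-frequency Markov chain.

Given the column-stochastic transition matrix ``M`` of
:mod:`fisdyn.kernel`, the distribution over genotypic states evolves as
``x_t = M^t x_0``.  This module propagates distributions, extracts the
steady state (dominant eigenvector), measures the mixing time in total
variation, solves the drift-only absorption problem, and summarises the
per-generation distribution of the inbreeding coefficient F_IS.

With ``mu > 0`` the chain is irreducible (mutation can regenerate any
genotype) and has a unique steady state.  With ``mu = 0`` lost alleles
never return; the fully clonal, mutation-free chain (``c = 1``) is the
pure-drift chain whose absorbing states are the ``g`` monomorphic-genotype
configurations — those are analysed by :func:`absorption_profile` rather
than by an eigenvector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kernel import TransitionMatrix
from .state_space import GenotypeState, ModelParams, StateSpace

__all__ = [
    "StateDistribution",
    "AnalysisConfig",
    "FisSummary",
    "AbsorptionProfile",
    "ReducibleChainError",
    "ConvergenceError",
    "propagate",
    "steady_state",
    "fis_summary",
    "mixing_time",
    "absorption_profile",
    "total_variation",
    "trajectory_table",
]


@dataclass(frozen=True)
class StateDistribution:
    """Probability vector over the enumerated state space at generation t."""

    probs: np.ndarray
    t: int | None = None

    def __post_init__(self) -> None:
        s = float(np.sum(self.probs))
        if not np.isclose(s, 1.0, atol=1e-8):
            raise ValueError(f"distribution sums to {s}, expected 1")
        if np.any(np.asarray(self.probs) < -1e-12):
            raise ValueError("distribution has negative entries")


@dataclass(frozen=True)
class AnalysisConfig:
    """Numerical knobs for chain analysis.

    ``epsilon`` is the acceptable error used as the convergence threshold;
    when ``None`` it defaults to ``1/(2N)``, half the minimal genotype
    frequency change resolvable by exhaustively sampling N individuals.
    """

    epsilon: float | None = None
    max_power_iterations: int = 200_000
    tol: float = 1e-12

    def resolve_epsilon(self, N: int) -> float:
        eps = 1.0 / (2.0 * N) if self.epsilon is None else self.epsilon
        if not 0.0 < eps < 1.0:
            raise ValueError(f"epsilon must lie in (0, 1), got {eps}")
        return eps


class ReducibleChainError(ValueError):
    """The chain has no unique steady state (mu = 0)."""


class ConvergenceError(RuntimeError):
    """Iteration budget exhausted; carries the best iterate found."""

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


def total_variation(x: np.ndarray, y: np.ndarray) -> float:
    """Total-variation distance between two probability vectors."""
    return 0.5 * float(np.abs(np.asarray(x) - np.asarray(y)).sum())


def _as_prob_vector(x0, space: StateSpace) -> np.ndarray:
    if isinstance(x0, StateDistribution):
        return np.asarray(x0.probs, dtype=float)
    if isinstance(x0, GenotypeState) or (
        not isinstance(x0, np.ndarray) and hasattr(x0, "__len__") and len(x0) == space.params.g
    ):
        return space.point_mass(x0)
    x0 = np.asarray(x0, dtype=float)
    if x0.shape == (len(space),):
        return x0
    if x0.shape == (space.params.g,):
        return space.point_mass(x0.astype(np.int64))
    raise ValueError(f"cannot interpret start of shape {x0.shape}")


def propagate(
    x0,
    tm: TransitionMatrix,
    t: int,
    return_all: bool = True,
) -> "list[StateDistribution] | StateDistribution":
    """Distributions ``x_s = M^s x_0`` for s = 0..t by repeated mat-vec.

    ``x0`` may be a :class:`StateDistribution`, a raw probability vector,
    or a genotypic state (count vector), which becomes a point mass.  With
    ``return_all=False`` only ``x_t`` is returned.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    x = _as_prob_vector(x0, tm.space)
    if x.shape[0] != len(tm):
        raise ValueError(f"dimension mismatch: |x0|={x.shape[0]}, |M|={len(tm)}")
    out = [StateDistribution(x.copy(), t=0)]
    for s in range(1, t + 1):
        x = tm.M @ x
        x /= x.sum()  # renormalise away accumulated rounding
        if return_all:
            out.append(StateDistribution(x.copy(), t=s))
    if return_all:
        return out
    return StateDistribution(x, t=t)


def _check_irreducible(tm: TransitionMatrix) -> None:
    p = tm.params
    if p.mu == 0.0:
        hint = (
            " (fully clonal drift-only chain: use absorption_profile)"
            if p.c == 1.0
            else " (allele loss is irreversible without mutation)"
        )
        raise ReducibleChainError(
            f"chain with mu=0 is reducible and has no unique steady state{hint}"
        )


def steady_state(
    tm: TransitionMatrix,
    cfg: AnalysisConfig | None = None,
    method: str = "power",
) -> StateDistribution:
    """Stationary distribution: the dominant eigenvector of M, normalised.

    ``method='power'`` iterates ``x <- M x`` until the successive-iterate
    total variation drops below ``cfg.tol``; ``method='linear'`` solves
    ``(M - I) x = 0`` with a normalisation row (used as a cross-check on
    small chains).  Requires ``mu > 0`` (irreducible chain).
    """
    cfg = cfg or AnalysisConfig()
    _check_irreducible(tm)
    S = len(tm)
    if method == "power":
        x = np.full(S, 1.0 / S)
        for _ in range(cfg.max_power_iterations):
            y = tm.M @ x
            y /= y.sum()
            if total_variation(x, y) < cfg.tol:
                return StateDistribution(y, t=None)
            x = y
        raise ConvergenceError(
            f"power iteration did not reach tol={cfg.tol} within "
            f"{cfg.max_power_iterations} iterations",
            partial=StateDistribution(x, t=None),
        )
    if method == "linear":
        A = tm.M - np.eye(S)
        A[-1, :] = 1.0
        b = np.zeros(S)
        b[-1] = 1.0
        x = np.linalg.solve(A, b)
        x = np.clip(x, 0.0, None)
        x /= x.sum()
        return StateDistribution(x, t=None)
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class FisSummary:
    """Distribution of F_IS implied by a state distribution.

    Moments and quantiles describe the *conditional* law of F_IS given the
    state is not excluded (fixed states — or near-fixed states, when that
    exclusion is selected — are removed and the remainder renormalised).
    ``p_fix`` and ``p_near_fix`` are reported unconditionally.  When all
    probability mass is excluded the conditional fields are ``None``.
    """

    mean: float | None
    variance: float | None
    q025: float | None
    q50: float | None
    q975: float | None
    p_fix: float
    p_near_fix: float
    excluded_mass: float
    histogram: list[tuple[float, float]] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.mean is not None


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    cum /= cum[-1]
    return float(v[np.searchsorted(cum, q, side="left").clip(0, len(v) - 1)])


def fis_summary(
    x: "StateDistribution | np.ndarray",
    space: StateSpace,
    exclude: str = "fixed",
) -> FisSummary:
    """Summarise the F_IS distribution carried by a state distribution.

    ``exclude`` is ``'fixed'`` (default: drop only single-allele states,
    where F_IS is undefined) or ``'near_fixed'`` (additionally drop states
    whose top allele frequency exceeds ``1 - sqrt(1/(2N))``, the rule used
    for multilocus sampling).
    """
    probs = x.probs if isinstance(x, StateDistribution) else np.asarray(x, dtype=float)
    d = space.descriptors()
    if exclude == "fixed":
        keep = d.defined
    elif exclude == "near_fixed":
        keep = d.defined & ~d.near_fixed
    else:
        raise ValueError(f"exclude must be 'fixed' or 'near_fixed', got {exclude!r}")
    p_fix = float(probs[d.fixed].sum())
    p_near_fix = float(probs[d.near_fixed].sum())
    w = probs * keep
    W = float(w.sum())
    if W <= 0.0:
        return FisSummary(
            mean=None, variance=None, q025=None, q50=None, q975=None,
            p_fix=p_fix, p_near_fix=p_near_fix, excluded_mass=1.0, histogram=[],
        )
    cond = w / W
    vals = d.fis
    kept = keep & (cond > 0)
    v, cw = vals[kept], cond[kept]
    mean = float(np.dot(v, cw))
    var = float(np.dot((v - mean) ** 2, cw))
    uniq, inv = np.unique(v, return_inverse=True)
    hist_w = np.bincount(inv, weights=cw, minlength=len(uniq))
    return FisSummary(
        mean=mean,
        variance=var,
        q025=_weighted_quantile(v, cw, 0.025),
        q50=_weighted_quantile(v, cw, 0.5),
        q975=_weighted_quantile(v, cw, 0.975),
        p_fix=p_fix,
        p_near_fix=p_near_fix,
        excluded_mass=1.0 - W,
        histogram=list(zip(uniq.tolist(), hist_w.tolist())),
    )


def mixing_time(
    tm: TransitionMatrix,
    cfg: AnalysisConfig | None = None,
    max_generations: int = 100_000,
) -> int:
    """Worst-case generations until within epsilon of the steady state.

    The smallest ``t`` such that the total-variation distance between
    ``M^t x_0`` and the stationary distribution is below epsilon for
    *every* pure start ``x_0``.  All pure starts are tracked at once by
    iterating ``X <- M X`` from the identity, so this is intended for
    chains small enough to enumerate exactly.
    """
    cfg = cfg or AnalysisConfig()
    eps = cfg.resolve_epsilon(tm.params.N)
    pi = steady_state(tm, cfg).probs
    S = len(tm)
    X = np.eye(S)
    for t in range(max_generations + 1):
        worst = 0.5 * np.abs(X - pi[:, None]).sum(axis=0).max()
        if worst < eps:
            return t
        X = tm.M @ X
    raise ConvergenceError(
        f"worst-case TV distance still {worst:.3g} >= eps={eps:.3g} after "
        f"{max_generations} generations",
        partial=int(max_generations),
    )


@dataclass(frozen=True)
class AbsorptionProfile:
    """First-passage analysis of the pure-drift (c=1, mu=0) chain.

    ``expected_times[s]`` is the expected number of generations until the
    population is genotypically uniform (all N individuals share one
    genotype) starting from state ``s``; zero on the absorbing states
    themselves.  ``hit_probs[s, k]`` is the probability of ending in the
    k-th absorbing state.  ``t_N`` is the maximum expected absorption time
    over all start states.
    """

    expected_times: np.ndarray
    hit_probs: np.ndarray
    absorbing_indices: np.ndarray
    t_N: float
    argmax_index: int


def absorption_profile(
    tm_or_params: "TransitionMatrix | ModelParams",
    cap: int | None = None,
) -> AbsorptionProfile:
    """Expected drift-absorption times from the standard linear system.

    Only valid for the drift-only configuration ``c = 1, mu = 0``.  The
    absorbing set is the ``g`` monomorphic-genotype states (final F_IS of
    0 via homozygote fixation or -1 via a surviving heterozygous clone);
    expected first-passage times solve ``(I - Q) t = 1`` on the transient
    block ``Q``.
    """
    if isinstance(tm_or_params, TransitionMatrix):
        tm = tm_or_params
    else:
        from .kernel import build_transition_matrix
        from .state_space import DEFAULT_STATE_CAP

        tm = build_transition_matrix(tm_or_params, cap=cap or DEFAULT_STATE_CAP)
    p = tm.params
    if not (p.c == 1.0 and p.mu == 0.0):
        raise ValueError(
            f"absorption_profile requires the drift-only chain (c=1, mu=0); "
            f"got c={p.c}, mu={p.mu}"
        )
    states = tm.space.states
    S = len(tm)
    absorbing = (states == p.N).any(axis=1)
    abs_idx = np.flatnonzero(absorbing)
    trans_idx = np.flatnonzero(~absorbing)
    times = np.zeros(S)
    hit = np.zeros((S, len(abs_idx)))
    hit[abs_idx, np.arange(len(abs_idx))] = 1.0
    if len(trans_idx):
        P = tm.M.T  # row convention: P[from, to]
        Q = P[np.ix_(trans_idx, trans_idx)]
        R = P[np.ix_(trans_idx, abs_idx)]
        A = np.eye(len(trans_idx)) - Q
        rhs = np.concatenate([np.ones((len(trans_idx), 1)), R], axis=1)
        sol = np.linalg.solve(A, rhs)
        times[trans_idx] = sol[:, 0]
        hit[trans_idx] = sol[:, 1:]
    k = int(np.argmax(times))
    return AbsorptionProfile(
        expected_times=times,
        hit_probs=hit,
        absorbing_indices=abs_idx,
        t_N=float(times[k]),
        argmax_index=k,
    )


def fis_histogram_table(
    distributions: "list[StateDistribution]",
    space: StateSpace,
) -> "pandas.DataFrame":  # noqa: F821
    """Full per-generation F_IS histograms: columns t, fis_value, probability.

    One row per distinct defined F_IS value with positive probability;
    the per-generation rows sum to 1 - P(fixed).
    """
    import pandas as pd

    rows = []
    for x in distributions:
        s = fis_summary(x, space, exclude="fixed")
        scale = 1.0 - s.excluded_mass
        for value, weight in s.histogram:
            rows.append({"t": x.t, "fis_value": value, "probability": weight * scale})
    return pd.DataFrame(rows)


def trajectory_table(
    distributions: "list[StateDistribution]",
    space: StateSpace,
    exclude: str = "fixed",
) -> "pandas.DataFrame":  # noqa: F821
    """Per-generation F_IS summary table for a propagated trajectory.

    Columns: t, mean_fis, var_fis, q2.5, q50, q97.5, p_fix, p_near_fix.
    Conditional fields are empty at generations where all mass is excluded.
    """
    import pandas as pd

    rows = []
    for x in distributions:
        s = fis_summary(x, space, exclude=exclude)
        rows.append(
            {
                "t": x.t,
                "mean_fis": s.mean,
                "var_fis": s.variance,
                "q2.5": s.q025,
                "q50": s.q50,
                "q97.5": s.q975,
                "p_fix": s.p_fix,
                "p_near_fix": s.p_near_fix,
            }
        )
    return pd.DataFrame(rows)
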