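"""Propagation, steady states, mixing and absorption of the exact chain."""

import itertools

import numpy as np
import pytest
import scipy.stats

from fisdyn import (
    AnalysisConfig,
    ModelParams,
    StateDistribution,
    absorption_profile,
    build_transition_matrix,
    enumerate_states,
    fis_summary,
    mixing_time,
    propagate,
    steady_state,
)
from fisdyn.chain import ReducibleChainError, total_variation
from fisdyn.kernel import step_deterministic


def scipy_pmf(to_counts, nu, N):
    """Independent multinomial pmf for the path-sum oracle."""
    return scipy.stats.multinomial.pmf(to_counts, n=N, p=nu)


class TestPropagate:
    def test_t_zero_returns_start(self, small_tm, small_space):
        x0 = small_space.point_mass((1, 1, 1))
        out = propagate(x0, small_tm, 0)
        assert len(out) == 1
        np.testing.assert_allclose(out[0].probs, x0)

    def test_identity_chain_is_static(self):
        params = ModelParams(N=1, n=2, c=1.0, mu=0.0)
        tm = build_transition_matrix(params)
        traj = propagate((0, 1, 0), tm, 5)
        for x in traj:
            np.testing.assert_allclose(x.probs, tm.space.point_mass((0, 1, 0)))

    def test_probability_conserved_every_step(self, small_tm):
        traj = propagate((1, 1, 1), small_tm, 30)
        for x in traj:
            assert x.probs.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_exhaustive_path_sum(self, small_params, small_space, small_tm):
        """x_4 from M^4 equals summing the probability of every length-4
        trajectory, each scored with an independent scipy multinomial pmf."""
        N = small_params.N
        start_idx = small_space.index_of((1, 1, 1))
        nus = [step_deterministic(s, small_params) for s in small_space.states]
        S = len(small_space)
        step_oracle = np.zeros((S, S))  # [to, from]
        for j in range(S):
            for i in range(S):
                step_oracle[i, j] = scipy_pmf(small_space.states[i], nus[j], N)
        target = np.zeros(S)
        for path in itertools.product(range(S), repeat=4):
            prob = step_oracle[path[0], start_idx]
            for a, b in zip(path, path[1:]):
                prob *= step_oracle[b, a]
            target[path[-1]] += prob
        x4 = propagate((1, 1, 1), small_tm, 4, return_all=False)
        np.testing.assert_allclose(x4.probs, target, atol=1e-10)

    def test_drift_only_expected_frequencies_are_martingale(self):
        params = ModelParams(N=5, n=2, c=1.0, mu=0.0)
        tm = build_transition_matrix(params)
        start = np.array([2, 2, 1])
        x1 = propagate(start, tm, 1, return_all=False)
        expected_nu = (tm.space.states.T @ x1.probs) / params.N
        np.testing.assert_allclose(expected_nu, start / 5, atol=1e-12)


class TestSteadyState:
    def test_power_agrees_with_linear_solve(self, small_tm):
        cfg = AnalysisConfig(tol=1e-13)
        a = steady_state(small_tm, cfg, method="power").probs
        b = steady_state(small_tm, cfg, method="linear").probs
        assert total_variation(a, b) < 1e-8

    def test_stationarity(self, small_tm):
        pi = steady_state(small_tm, AnalysisConfig(tol=1e-13)).probs
        np.testing.assert_allclose(small_tm.M @ pi, pi, atol=1e-10)

    def test_symmetric_under_allele_relabelling(self):
        # N=1, maximal mutation: exchanging the allele labels permutes the
        # states (aa <-> AA) and must leave the steady distribution unchanged
        params = ModelParams(N=1, n=2, c=0.5, mu=0.5)
        tm = build_transition_matrix(params)
        pi = steady_state(tm, AnalysisConfig(tol=1e-14)).probs
        assert pi[0] == pytest.approx(pi[2], abs=1e-10)

    def test_reducible_chain_refused(self):
        tm = build_transition_matrix(ModelParams(N=2, n=2, c=1.0, mu=0.0))
        with pytest.raises(ReducibleChainError, match="absorption_profile"):
            steady_state(tm)


class TestFisSummary:
    def test_point_mass_on_hwe(self, ):
        params = ModelParams(N=100, n=2, c=0.0, mu=0.01)
        space = enumerate_states(params)
        s = fis_summary(space.point_mass((25, 50, 25)), space)
        assert s.mean == pytest.approx(0.0, abs=1e-12)
        assert s.variance == pytest.approx(0.0, abs=1e-12)
        assert s.p_fix == 0.0

    def test_point_mass_on_fixed_state_is_undefined(self):
        params = ModelParams(N=100, n=2)
        space = enumerate_states(params)
        s = fis_summary(space.point_mass((100, 0, 0)), space)
        assert not s.defined
        assert s.mean is None
        assert s.p_fix == pytest.approx(1.0)

    def test_mixture_mean(self):
        params = ModelParams(N=100, n=2)
        space = enumerate_states(params)
        x = 0.5 * space.point_mass((0, 100, 0)) + 0.5 * space.point_mass((25, 50, 25))
        s = fis_summary(x, space)
        assert s.mean == pytest.approx(-0.5)
        assert s.q025 == pytest.approx(-1.0)
        assert s.q975 == pytest.approx(0.0)

    def test_near_fixed_exclusion_renormalises(self):
        params = ModelParams(N=100, n=2)
        space = enumerate_states(params)
        # (95,5,0) is near-fixed (p = 0.975) but not fixed
        x = 0.5 * space.point_mass((95, 5, 0)) + 0.5 * space.point_mass((25, 50, 25))
        s_fixed = fis_summary(x, space, exclude="fixed")
        s_near = fis_summary(x, space, exclude="near_fixed")
        assert s_near.mean == pytest.approx(0.0, abs=1e-12)
        assert s_fixed.mean != pytest.approx(0.0, abs=1e-6)
        assert s_near.p_near_fix == pytest.approx(0.5)


def test_fis_histogram_table_masses(small_tm, small_space):
    from fisdyn.chain import fis_histogram_table

    traj = propagate((1, 1, 1), small_tm, 3)
    df = fis_histogram_table(traj, small_space)
    assert set(df.columns) == {"t", "fis_value", "probability"}
    for t, group in df.groupby("t"):
        p_fix = fis_summary(traj[t], small_space).p_fix
        assert group["probability"].sum() == pytest.approx(1.0 - p_fix, abs=1e-10)


def test_transition_matrix_cache_roundtrip(tmp_path, small_tm, small_params):
    from fisdyn.kernel import TransitionMatrix

    assert TransitionMatrix.load(small_params, tmp_path) is None
    small_tm.save(tmp_path)
    back = TransitionMatrix.load(small_params, tmp_path)
    np.testing.assert_array_equal(back.M, small_tm.M)
    assert back.params == small_params


class TestMixingTime:
    def test_definition_boundary(self, small_tm, small_params):
        cfg = AnalysisConfig()
        eps = cfg.resolve_epsilon(small_params.N)
        t = mixing_time(small_tm, cfg)
        pi = steady_state(small_tm, AnalysisConfig(tol=1e-13)).probs
        S = len(small_tm)
        worst = lambda P: 0.5 * np.abs(P - pi[:, None]).sum(axis=0).max()
        Mt = np.linalg.matrix_power(small_tm.M, t)
        assert worst(Mt) < eps
        if t > 0:
            assert worst(np.linalg.matrix_power(small_tm.M, t - 1)) >= eps

    def test_tv_distance_monotone_nonincreasing(self, small_tm):
        pi = steady_state(small_tm, AnalysisConfig(tol=1e-13)).probs
        x = small_tm.space.point_mass((3, 0, 0))
        prev = total_variation(x, pi)
        for _ in range(40):
            x = small_tm.M @ x
            cur = total_variation(x, pi)
            assert cur <= prev + 1e-12
            prev = cur

    def test_clonality_never_speeds_mixing(self):
        # full-distribution mixing is limited by the mutation mode, which
        # clonality cannot accelerate: non-decreasing in c
        times = []
        for c in [0.0, 0.5, 0.9]:
            tm = build_transition_matrix(ModelParams(N=3, n=2, c=c, mu=0.01))
            times.append(mixing_time(tm))
        assert all(a <= b for a, b in zip(times, times[1:]))

    def test_clonality_slows_convergence_to_the_mean(self):
        # the c-sensitive slowdown acts on the mean F_IS trajectory: from a
        # homozygote-excess start the generations needed to settle within
        # 1/(2N) of the final mean grow strictly with c
        def mean_conv_time(c, N=4, mu=0.01, t_max=400):
            params = ModelParams(N=N, n=2, c=c, mu=mu)
            tm = build_transition_matrix(params)
            pi = steady_state(tm, AnalysisConfig(tol=1e-13))
            target = fis_summary(pi, tm.space).mean
            eps = 1.0 / (2.0 * N)
            means = [fis_summary(x, tm.space).mean for x in propagate((2, 0, 2), tm, t_max)]
            outside = [i for i, m in enumerate(means) if m is None or abs(m - target) >= eps]
            return (outside[-1] + 1) if outside else 0

        times = [mean_conv_time(c) for c in [0.0, 0.5, 0.9, 0.99]]
        assert times == sorted(times)
        assert times[0] < times[-1]

    def test_weak_chain_small_mixing_time(self):
        tm = build_transition_matrix(ModelParams(N=1, n=2, c=1.0, mu=0.5))
        assert mixing_time(tm) <= 25


class TestAbsorption:
    def test_single_individual_all_absorbing(self):
        prof = absorption_profile(ModelParams(N=1, n=2, c=1.0, mu=0.0))
        np.testing.assert_allclose(prof.expected_times, 0.0)
        assert prof.t_N == 0.0

    def test_two_individual_closed_form(self):
        # from (1,1,0): stays with prob 1/2, absorbs otherwise -> E[T] = 2
        prof = absorption_profile(ModelParams(N=2, n=2, c=1.0, mu=0.0))
        space = enumerate_states(ModelParams(N=2, n=2))
        idx = space.index_of((1, 1, 0))
        assert prof.expected_times[idx] == pytest.approx(2.0)

    def test_hit_probabilities_sum_to_one(self):
        prof = absorption_profile(ModelParams(N=4, n=2, c=1.0, mu=0.0))
        np.testing.assert_allclose(prof.hit_probs.sum(axis=1), 1.0, atol=1e-10)

    def test_requires_drift_only_configuration(self):
        with pytest.raises(ValueError, match="drift-only"):
            absorption_profile(ModelParams(N=3, n=2, c=1.0, mu=0.01))
        with pytest.raises(ValueError, match="drift-only"):
            absorption_profile(ModelParams(N=3, n=2, c=0.5, mu=0.0))

    def test_absorbing_set_is_monomorphic_genotypes(self):
        params = ModelParams(N=4, n=2, c=1.0, mu=0.0)
        prof = absorption_profile(params)
        space = enumerate_states(params)
        for idx in prof.absorbing_indices:
            assert (space.states[idx] == 4).any()
        assert len(prof.absorbing_indices) == 3
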