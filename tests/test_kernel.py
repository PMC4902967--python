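"""Deterministic frequency maps and the multinomial transition law."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fisdyn import (
    ModelParams,
    build_transition_matrix,
    describe_state,
    gamete_frequencies,
    mutate,
    reproduce,
    step_deterministic,
    transition_probability,
)
from fisdyn.state_space import enumerate_states, genotype_pairs


def random_nu(draw_ints, g):
    """Frequency vector from a list of non-negative integers (at least one > 0)."""
    total = sum(draw_ints)
    return np.array(draw_ints, dtype=float) / total


def mutation_oracle(nu, params):
    """Independent construction: expand to ordered allele pairs, apply the
    n x n substitution matrix to each slot, re-collapse to unordered
    genotypes."""
    n = params.n
    pairs = genotype_pairs(n)
    U = np.full((n, n), params.beta)
    np.fill_diagonal(U, params.alpha)
    S = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        if i == j:
            S[i, i] = nu[k]
        else:
            S[i, j] = S[j, i] = nu[k] / 2.0
    S2 = U @ S @ U.T
    out = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        out[k] = S2[i, i] if i == j else 2.0 * S2[i, j]
    return out


nu_ints = lambda g: st.lists(st.integers(0, 20), min_size=g, max_size=g).filter(
    lambda q: sum(q) > 0
)


class TestMutate:
    def test_mu_zero_is_identity(self):
        nu = np.array([0.3, 0.5, 0.2])
        np.testing.assert_allclose(mutate(nu, ModelParams(N=10, n=2, mu=0.0)), nu)

    @pytest.mark.parametrize("nu", [(0, 1, 0), (1, 0, 0)])
    def test_maximal_mutation_fully_symmetrises(self, nu):
        # alpha = beta = 1/2: both allele slots become uniform coin flips
        out = mutate(np.array(nu, dtype=float), ModelParams(N=10, n=2, mu=0.5))
        np.testing.assert_allclose(out, [0.25, 0.5, 0.25], atol=1e-14)

    @settings(max_examples=150, deadline=None)
    @given(
        n=st.sampled_from([2, 3, 4]),
        data=st.data(),
        mu_scale=st.floats(0.0, 1.0),
    )
    def test_equivalent_to_per_allele_substitution(self, n, data, mu_scale):
        g = n * (n + 1) // 2
        nu = random_nu(data.draw(nu_ints(g)), g)
        params = ModelParams(N=10, n=n, mu=mu_scale * (n - 1) / n)
        out = mutate(nu, params)
        np.testing.assert_allclose(out, mutation_oracle(nu, params), atol=1e-12)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mutation_only_iteration_reaches_uniform_alleles(self):
        # the k-alleles steady state is F_IS = 0 at equal allele frequencies
        params = ModelParams(N=10, n=3, mu=0.05)
        nu = np.zeros(6)
        nu[0] = 1.0  # start fixed on A1A1
        for _ in range(2000):
            nu = mutate(nu, params)
        p = gamete_frequencies(nu)
        np.testing.assert_allclose(p, 1 / 3, atol=1e-10)
        # genotype frequencies are the HWE products of uniform alleles
        hom = nu[[0, 3, 5]]
        np.testing.assert_allclose(hom, 1 / 9, atol=1e-10)


class TestGametesAndReproduction:
    @pytest.mark.parametrize(
        "nu,p",
        [
            ((0, 1, 0), (0.5, 0.5)),
            ((1, 0, 0), (1.0, 0.0)),
            ((0.25, 0.5, 0.25), (0.5, 0.5)),
        ],
    )
    def test_gamete_frequencies(self, nu, p):
        np.testing.assert_allclose(gamete_frequencies(np.array(nu, float)), p)

    def test_full_clonality_is_identity(self):
        nu = np.array([0.1, 0.7, 0.2])
        np.testing.assert_allclose(reproduce(nu, ModelParams(N=10, n=2, c=1.0)), nu)

    def test_one_sexual_generation_reaches_hwe(self):
        out = reproduce(np.array([0.0, 1.0, 0.0]), ModelParams(N=10, n=2, c=0.0))
        np.testing.assert_allclose(out, [0.25, 0.5, 0.25])

    def test_intermediate_clonality_mixes_linearly(self):
        out = reproduce(np.array([0.0, 1.0, 0.0]), ModelParams(N=10, n=2, c=0.5))
        np.testing.assert_allclose(out, [0.125, 0.75, 0.125])

    @settings(max_examples=100, deadline=None)
    @given(n=st.sampled_from([2, 3]), data=st.data())
    def test_sexual_output_lands_on_hwe_parabola(self, n, data):
        g = n * (n + 1) // 2
        nu = random_nu(data.draw(nu_ints(g)), g)
        params = ModelParams(N=10, n=n, c=0.0)
        out = reproduce(nu, params)
        p = gamete_frequencies(out)
        # F_IS of the output is exactly 0 whenever polymorphic
        He = 1.0 - (p**2).sum()
        if He > 1e-12:
            pairs = genotype_pairs(n)
            Ho = sum(out[k] for k, (i, j) in enumerate(pairs) if i != j)
            assert (He - Ho) / He == pytest.approx(0.0, abs=1e-10)

    @settings(max_examples=100, deadline=None)
    @given(
        n=st.sampled_from([2, 3]),
        data=st.data(),
        c=st.floats(0.0, 1.0),
        mu_scale=st.floats(0.0, 1.0),
    )
    def test_frequency_conservation_through_all_maps(self, n, data, c, mu_scale):
        g = n * (n + 1) // 2
        nu = random_nu(data.draw(nu_ints(g)), g)
        params = ModelParams(N=10, n=n, c=c, mu=mu_scale * (n - 1) / n)
        assert mutate(nu, params).sum() == pytest.approx(1.0, abs=1e-12)
        assert reproduce(nu, params).sum() == pytest.approx(1.0, abs=1e-12)
        assert gamete_frequencies(nu).sum() == pytest.approx(1.0, abs=1e-12)


class TestStepDeterministic:
    def test_drift_only_returns_current_frequencies(self):
        params = ModelParams(N=4, n=2, c=1.0, mu=0.0)
        np.testing.assert_allclose(
            step_deterministic(np.array([1, 2, 1]), params), [0.25, 0.5, 0.25]
        )

    def test_sexual_step_from_all_heterozygotes(self):
        params = ModelParams(N=100, n=2, c=0.0, mu=0.0)
        np.testing.assert_allclose(
            step_deterministic(np.array([0, 100, 0]), params), [0.25, 0.5, 0.25]
        )

    def test_hwe_is_near_fixed_point_under_weak_mutation(self):
        params = ModelParams(N=100, n=2, c=0.8, mu=1e-6)
        out = step_deterministic(np.array([25, 50, 25]), params)
        np.testing.assert_allclose(out, [0.25, 0.5, 0.25], atol=1e-5)


def factorial_pmf_oracle(q_to, nu):
    """Multinomial pmf straight from the factorial formula (exact coefficient)."""
    N = sum(q_to)
    coef = Fraction(math.factorial(N))
    for q in q_to:
        coef /= math.factorial(q)
    return float(coef) * math.prod(p**q for p, q in zip(nu, q_to))


class TestTransitionProbabilities:
    def test_heterozygote_clone_is_certain(self):
        params = ModelParams(N=1, n=2, c=1.0, mu=0.0)
        assert transition_probability((0, 1, 0), (0, 1, 0), params) == pytest.approx(1.0)

    def test_two_individual_drift_example(self):
        params = ModelParams(N=2, n=2, c=1.0, mu=0.0)
        # nu = (1/2, 1/2, 0); P(both land on A1A1) = (1/2)^2
        assert transition_probability((1, 1, 0), (2, 0, 0), params) == pytest.approx(0.25)

    def test_rows_normalise(self, small_params, small_space):
        for row in small_space.states[::3]:
            total = sum(
                transition_probability(row, to, small_params) for to in small_space.states
            )
            assert total == pytest.approx(1.0, abs=1e-12)


class TestTransitionMatrix:
    def test_identity_for_frozen_single_individual(self):
        tm = build_transition_matrix(ModelParams(N=1, n=2, c=1.0, mu=0.0))
        np.testing.assert_allclose(tm.M, np.eye(3))

    @pytest.mark.parametrize(
        "params",
        [
            ModelParams(N=2, n=2, c=0.0, mu=0.0),
            ModelParams(N=3, n=2, c=0.5, mu=0.01),
            ModelParams(N=2, n=3, c=0.9, mu=0.1),
        ],
    )
    def test_columns_are_stochastic(self, params):
        tm = build_transition_matrix(params)
        np.testing.assert_allclose(tm.M.sum(axis=0), 1.0, atol=1e-10)
        assert (tm.M >= 0).all() and (tm.M <= 1).all()

    def test_entries_match_factorial_oracle(self):
        params = ModelParams(N=3, n=2, c=0.5, mu=0.01)
        space = enumerate_states(params)
        tm = build_transition_matrix(params, space=space)
        for j in range(len(space)):
            nu = step_deterministic(space.states[j], params)
            for i in range(len(space)):
                expected = factorial_pmf_oracle(tuple(space.states[i]), nu)
                assert tm.M[i, j] == pytest.approx(expected, abs=1e-13)

    def test_positive_mutation_makes_chain_irreducible(self, small_tm):
        assert (small_tm.M > 0).all()

    def test_sparse_table_roundtrip(self, small_tm):
        df = small_tm.to_table()
        rebuilt = np.zeros_like(small_tm.M)
        rebuilt[df["state_index_to"], df["state_index_from"]] = df["probability"]
        np.testing.assert_allclose(rebuilt, small_tm.M)
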