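"""Shared fixtures: small exactly-solvable chains used across test modules."""

import pytest

from fisdyn import ModelParams, build_transition_matrix, enumerate_states


@pytest.fixture(scope="session")
def small_params():
    """A 10-state biallelic chain (N=3) with all three forces active."""
    return ModelParams(N=3, n=2, c=0.5, mu=0.01)


@pytest.fixture(scope="session")
def small_space(small_params):
    return enumerate_states(small_params)


@pytest.fixture(scope="session")
def small_tm(small_params, small_space):
    return build_transition_matrix(small_params, space=small_space)
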