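import logging

import pytest

from momentfba import (
    build_moment,
    chain_toy,
    complex_toy,
    isozyme_toy,
    solve_moment,
)

logging.getLogger("momentfba").setLevel(logging.ERROR)


@pytest.fixture
def chain():
    """Single-enzyme chain: kcat 100/h, MW 1 g/mmol, C 0.5 -> growth 50."""
    return chain_toy(kcats=(100.0,), mws=(1.0,), C=0.5)


@pytest.fixture
def isozyme():
    """Isozyme pair (gA or gB), kcat 10/h, MW 1 and 2, C 1 -> growth 10."""
    return isozyme_toy(kcat=10.0, mws=(1.0, 2.0), C=1.0)


@pytest.fixture
def complex_pair():
    """Two-subunit complex (gA and gB), kcat 10/h, MW 1 and 3, C 1 -> 2.5."""
    return complex_toy(kcat=10.0, mws=(1.0, 3.0), C=1.0)


def moment_growth(toy, **kwargs):
    sol = solve_moment(build_moment(toy.model, toy.params, toy.medium), **kwargs)
    assert sol.optimal, sol.status
    return sol.growth
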