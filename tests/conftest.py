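import random

import pytest

from ssosort.perm import SignedPermutation, CIRCULAR


@pytest.fixture
def pi5() -> SignedPermutation:
    """The five-element permutation used by the worked crossing example."""
    return SignedPermutation((4, 2, 3, -1, -5))


@pytest.fixture
def pi6() -> SignedPermutation:
    """Six-element permutation whose minimum-cn vector set is not fully
    generated by single-step contracting moves."""
    return SignedPermutation((4, 5, 3, 1, -2, -6))


@pytest.fixture
def pi14() -> SignedPermutation:
    """Fourteen-element permutation whose optimal vector lies outside the
    minimum-crossing-number set."""
    return SignedPermutation((-1, -2, 12, -4, -5, -6, -7, 3, 9, 10, 11, 8, -13, -14))


@pytest.fixture
def circ5() -> SignedPermutation:
    return SignedPermutation((5, 4, -2, -1, 3), topology=CIRCULAR)


def random_signed(n: int, rng: random.Random) -> SignedPermutation:
    base = list(range(1, n + 1))
    rng.shuffle(base)
    return SignedPermutation(tuple(rng.choice((1, -1)) * v for v in base))
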