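import random

import pytest

from ssosort.displacement import (
    CONTRACTING,
    NONE,
    STRICTLY_CONTRACTING,
    DisplacementVector,
    contraction_type,
    crossing_matrix,
    crossing_number,
    crossing_value,
    initial_vd,
    minimize_crossing,
    sequence_displacement,
    swap_update,
    transform,
    validate_vd,
)
from ssosort.errors import SizeError, ValidityError
from ssosort.perm import (
    REVERSAL,
    TRANSPOSITION,
    Operation,
    SortingSequence,
    identity,
)
from .conftest import random_signed


def random_valid_vector(n: int, rng: random.Random) -> DisplacementVector:
    """A valid vector for a random permutation, shifted by random turns."""
    pi = random_signed(n, rng)
    x = list(initial_vd(pi).x)
    for _ in range(rng.randint(0, 4)):
        i, j = rng.sample(range(n), 2)
        x[i] -= n
        x[j] += n
    return DisplacementVector(tuple(x)), pi


class TestInitialAndValidity:
    def test_worked_example(self, pi5):
        assert initial_vd(pi5).x == (3, 0, 0, -3, 0)

    def test_identity_is_zero(self):
        assert initial_vd(identity(6)).x == (0,) * 6

    def test_large_example(self, pi14):
        assert initial_vd(pi14).x == (0, 0, 9, 0, 0, 0, 0, -5, 0, 0, 0, -4, 0, 0)

    def test_validate(self, pi5):
        assert validate_vd(DisplacementVector((3, 0, 0, -3, 0)), pi5)
        assert validate_vd(DisplacementVector((-2, 0, 0, 2, 0)), pi5)
        # off-by-one entry no longer matches positions mod n
        assert not validate_vd(DisplacementVector((3, 0, 1, -3, -1)), pi5)

    def test_nonzero_sum_rejected_at_construction(self):
        with pytest.raises(ValidityError):
            DisplacementVector((3, 0, 0, -3, 1))

    def test_length_mismatch(self, pi5):
        with pytest.raises(SizeError):
            validate_vd(DisplacementVector((0, 0)), pi5)


class TestCrossingValues:
    def test_worked_values(self):
        X = DisplacementVector((3, 0, 0, -3, 0))
        assert crossing_value(X, 2, 4) == 1
        assert crossing_value(X, 3, 1) == -1
        assert crossing_value(X, 4, 2) == -1  # antisymmetry

    def test_diagonal_undefined(self):
        with pytest.raises(ValidityError):
            crossing_value(DisplacementVector((0, 0)), 1, 1)

    def test_crossing_number_examples(self):
        assert crossing_number(DisplacementVector((3, 0, 0, -3, 0))) == 5
        assert crossing_number(DisplacementVector((-2, 0, 0, 2, 0))) == 3
        assert crossing_number(DisplacementVector((0,) * 5)) == 0

    def test_displacement_consistency_random(self):
        rng = random.Random(21)
        for _ in range(100):
            X, _ = random_valid_vector(rng.randint(2, 12), rng)
            c = crossing_matrix(X)
            for i in range(1, X.n + 1):
                assert sum(c[(i, j)] for j in range(1, X.n + 1) if j != i) == X[i]


class TestTransform:
    def test_worked_transform(self):
        X = DisplacementVector((3, 0, 0, -3, 0))
        assert transform(X, 1, 4).x == (-2, 0, 0, 2, 0)

    def test_inverse_pair(self):
        X = DisplacementVector((3, 0, 0, -3, 0))
        assert transform(transform(X, 1, 4), 4, 1) == X

    def test_fig5_transform(self, pi14):
        X1 = initial_vd(pi14)
        assert transform(X1, 3, 12).x == (0, 0, -5, 0, 0, 0, 0, -5, 0, 0, 0, 10, 0, 0)

    def test_contraction_classification(self):
        X = DisplacementVector((3, 0, 0, -3, 0))
        assert contraction_type(X, 1, 4) == STRICTLY_CONTRACTING
        X6 = DisplacementVector((3, 3, 0, -3, -3, 0))
        assert contraction_type(X6, 1, 4) == CONTRACTING
        assert contraction_type(DisplacementVector((0, 0)), 1, 2) == NONE

    def test_conservation_law_in_single_crossing_regime(self):
        # cn(T_{i,j}(X)) = cn(X) + 2(n - x_i + x_j) holds whenever pi_i
        # crosses every element at most once rightward, pi_j at most once
        # leftward, and c_ij = 1 (the regime the minimization operates in)
        rng = random.Random(33)
        checked = 0
        while checked < 200:
            X, _ = random_valid_vector(rng.randint(2, 12), rng)
            n = X.n
            for i in range(1, n + 1):
                for j in range(1, n + 1):
                    if i == j or crossing_value(X, i, j) != 1:
                        continue
                    others = [b for b in range(1, n + 1) if b not in (i, j)]
                    if not all(crossing_value(X, i, b) in (0, 1) for b in others):
                        continue
                    if not all(crossing_value(X, j, b) in (-1, 0) for b in others):
                        continue
                    assert crossing_number(transform(X, i, j)) == crossing_number(
                        X
                    ) + 2 * (n - X[i] + X[j])
                    checked += 1

    def test_conservation_law_needs_its_side_conditions(self):
        # outside the single-crossing regime the law fails: transforming the
        # zero vector of iota_3 yields (-3,3,0), whose true crossing number
        # is 4 (elements 1 and 2 loop once around and cross twice, each
        # crosses element 3 once) although the formula predicts 6
        Z = DisplacementVector((0, 0, 0))
        Y = transform(Z, 1, 2)
        assert Y.x == (-3, 3, 0)
        assert abs(crossing_value(Y, 1, 2)) == 2
        assert crossing_number(Y) == 4
        assert crossing_number(Y) != crossing_number(Z) + 2 * (3 - Z[1] + Z[2])

    def test_minimized_vectors_cn_laws(self):
        # at a minimized vector, difference-n transforms preserve cn and all
        # other transforms strictly increase it (what candidate-set
        # enumeration relies on)
        rng = random.Random(34)
        for _ in range(60):
            X, _ = random_valid_vector(rng.randint(2, 10), rng)
            Xm = minimize_crossing(X)
            cn = crossing_number(Xm)
            n = Xm.n
            for i in range(1, n + 1):
                for j in range(1, n + 1):
                    if i == j:
                        continue
                    cn2 = crossing_number(transform(Xm, i, j))
                    if Xm[i] - Xm[j] == n:
                        assert cn2 == cn
                    else:
                        assert cn2 > cn


class TestMinimizeCrossing:
    def test_single_step(self):
        X = DisplacementVector((3, 0, 0, -3, 0))
        Xm = minimize_crossing(X)
        assert Xm.x == (-2, 0, 0, 2, 0)
        assert crossing_number(Xm) == 3

    def test_fixed_point_unchanged(self, pi6):
        X = initial_vd(pi6)  # (3,3,0,-3,-3,0): max spread equals n, no strict move
        assert minimize_crossing(X) == X
        assert crossing_number(X) == 8

    def test_zero_vector(self):
        Z = DisplacementVector((0,) * 4)
        assert minimize_crossing(Z) == Z

    def test_fixed_point_is_global_minimum(self):
        # no strictly contracting move may remain, and no single transform improves
        rng = random.Random(17)
        for _ in range(100):
            X, _ = random_valid_vector(rng.randint(2, 10), rng)
            Xm = minimize_crossing(X)
            assert max(Xm.x) - min(Xm.x) <= Xm.n
            cn = crossing_number(Xm)
            for i in range(1, Xm.n + 1):
                for j in range(1, Xm.n + 1):
                    if i != j:
                        assert crossing_number(transform(Xm, i, j)) >= cn

    def test_order_independence_of_final_cn(self):
        rng = random.Random(71)
        for _ in range(30):
            X, _ = random_valid_vector(rng.randint(3, 9), rng)
            target = crossing_number(minimize_crossing(X))
            # random application order of strictly contracting moves
            Y = X
            while True:
                pairs = [
                    (i, j)
                    for i in range(1, Y.n + 1)
                    for j in range(1, Y.n + 1)
                    if i != j and Y[i] - Y[j] > Y.n
                ]
                if not pairs:
                    break
                Y = transform(Y, *rng.choice(pairs))
            assert crossing_number(Y) == target


class TestSwapUpdate:
    def test_worked_update(self):
        X = DisplacementVector((-2, 0, 0, 2, 0))
        assert swap_update(X, 4).x == (-2, 0, 0, 1, 1)
        assert crossing_number(swap_update(X, 4)) == crossing_number(X) - 1

    def test_non_induced_rejected(self):
        X = DisplacementVector((-2, 0, 0, 2, 0))
        with pytest.raises(ValidityError):
            swap_update(X, 2)

    def test_update_matches_full_recount(self):
        rng = random.Random(55)
        checked = 0
        while checked < 60:
            X, _ = random_valid_vector(rng.randint(2, 9), rng)
            for p in range(1, X.n + 1):
                q = p % X.n + 1
                if q != p and crossing_value(X, p, q) > 0:
                    Y = swap_update(X, p)
                    assert crossing_number(Y) == crossing_number(X) - 1
                    checked += 1
                    break


class TestSequenceDisplacement:
    def test_worked_sequence(self, pi5):
        S = SortingSequence(
            (
                Operation(REVERSAL, (3, 4)),
                Operation(TRANSPOSITION, (2, 3, 4)),
                Operation(TRANSPOSITION, (1, 2, 3)),
                Operation(TRANSPOSITION, (2, 3, 4)),
                Operation(REVERSAL, (3, 4)),
                Operation(REVERSAL, (4, 4)),
                Operation(REVERSAL, (5, 5)),
            ),
            pi5,
        )
        V = sequence_displacement(pi5, S)
        assert V.x == (3, 0, 0, -3, 0)
        # the element -1 sits at position 4 of pi: moved left three times
        assert V[4] == -3

    def test_empty_sequence_on_identity(self):
        S = SortingSequence((), identity(4))
        assert sequence_displacement(identity(4), S).x == (0, 0, 0, 0)

    def test_replayed_vector_is_valid(self, pi5):
        from ssosort.distance import linear_cyclic_distance

        res = linear_cyclic_distance(pi5, with_sequence=True)
        V = sequence_displacement(pi5, res.sequence)
        assert validate_vd(V, pi5)
        assert V == res.witness_vector
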